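"""Run configuration shared by the pipeline stages and the CLI.

Every default that has a stated protocol value uses it: 3 Hz / 4th-order
zero-lag low-pass, 3 s segment trim, 70 % subject and 70 % feature
resampling over 500 iterations with a 50 % consistency threshold, AUC at
the distribution median, 90 % target sensitivity, 1,000 k-means restarts
and a 10-fold x 500-repetition baseline protocol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    # signal stage
    sampling_rate: float = 100.0          # Hz
    filter_cutoff: float = 3.0            # Hz
    filter_order: int = 4
    trim_seconds: float = 3.0
    wavelet_scale: float | None = None    # None = match step frequency
    distance: float = 20.0                # m per walking direction

    # cognitive index stage
    kmeans_repeats: int = 1000
    age_threshold: float = 60.0
    normative_n: int = 300

    # stable-sparse-classifier stage
    ssc_n_iter: int = 500
    validation_n_iter: int = 500
    subject_fraction: float = 0.7
    feature_fraction: float = 0.7
    consistency_threshold: float = 0.5
    screening_keep_fraction: float = 0.5
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5
    one_se: bool = True
    target_sensitivity: float = 0.90

    # evaluation stage
    baseline_folds: int = 10
    baseline_reps: int = 500
    n_permutations: int = 999
    alpha: float = 0.05

    # orchestration
    models: list[str] = field(default_factory=lambda: ["__all__"])
    comparison: tuple[str, str] = ("HE", "MCI-E")
    seed: int = 0
    output_dir: str = "runs/latest"

    def enet_config(self):
        from .enet import ElasticNetConfig

        return ElasticNetConfig(gamma=self.gamma, n_lambdas=self.n_lambdas,
                                lambda_min_ratio=self.lambda_min_ratio,
                                n_folds=self.cv_folds, one_se=self.one_se)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["comparison"] = list(d["comparison"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "comparison" in d:
            d["comparison"] = tuple(d["comparison"])
        return cls(**d)

    def digest(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        d["comparison"] = list(d["comparison"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str, *extra) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the root seed.

        The derivation hashes the stage name (and any extra keys such as
        subject and task identifiers) into entropy that is combined with
        the root seed, so any stage can be rerun in isolation and still
        see the stream it saw in the full run.
        """
        key = hashlib.sha256(
            ("/".join([stage, *map(str, extra)])).encode()).digest()
        words = [int.from_bytes(key[i:i + 4], "little") for i in (0, 4, 8)]
        return np.random.SeedSequence([self.seed, *words])

    def stage_int_seed(self, stage: str, *extra) -> int:
        """A plain integer seed (< 2**31) for APIs that need one."""
        return int(self.stage_seed(stage, *extra).generate_state(1)[0]
                   % (2 ** 31))
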