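"""Challenge configuration: one validated object drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from petrelease.acquisition import (
    CARBON11_HALF_LIFE_MIN,
    DEFAULT_FRAMING_SCHEME,
    Framing,
    ScannerModel,
    make_framing,
)
from petrelease.recon import ReconConfig

__all__ = ["ChallengeConfig", "PAPER_BRAIN_VOLUME_MM3"]

#: adult brain volume (mm^3) to which the full-scale count budget refers
PAPER_BRAIN_VOLUME_MM3 = 1.4e6


@dataclass
class ChallengeConfig:
    """Study conditions of a simulated displacement experiment.

    Defaults reproduce the challenge design at desk scale: 5 subjects
    scanned pre and post challenge, a 23-frame 90-minute protocol, 20%/25%
    randoms/scatter, MLEM reconstruction with a 2.5 mm PSF.

    ``total_counts`` may be a number, or ``"match_density"`` to scale the
    full-protocol 3e8-count budget by the ratio of the phantom brain volume
    to a 1.4e6 mm^3 adult brain, preserving the per-volume noise level of
    the full-scale experiment.
    """

    n_subjects: int = 5
    grid_shape: tuple = (64, 64, 48)
    voxel_size_mm: float = 2.0
    framing_scheme: tuple = DEFAULT_FRAMING_SCHEME
    half_life_min: float = CARBON11_HALF_LIFE_MIN
    total_counts: float | str = 3e6
    randoms_fraction: float = 0.20
    scatter_fraction: float = 0.25
    scatter_fwhm_mm: float = 40.0
    n_angles: int | None = None
    acquisition_psf_fwhm_mm: float = 2.5
    recon_iterations: int = 30
    recon_psf_fwhm_mm: float = 2.5
    quant_method: str = "srtm"
    quant_pre_smoothing_fwhm_mm: float = 8.0
    stat_test: str = "perm"
    n_perm: int = 10000
    alpha: float = 0.05
    stat_smoothing_fwhm_mm: float = 0.0
    variance_smoothing_fwhm_mm: float = 5.0
    cluster_extent: int = 0
    connectivity: int = 18
    seed: int = 0
    phantom_kwargs: dict = field(default_factory=dict)
    roi_sizes_mm3: tuple = (2555.0, 2275.0, 1152.0, 493.0, 343.0, 418.0)
    roi_deltas: tuple = (0.27, 0.27, 0.21, 0.18, 0.18, 0.18)
    roi_baseline_bp: tuple = (1.39, 1.65, 0.78, 1.16, 2.02, 0.67)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        fr, fs = self.randoms_fraction, self.scatter_fraction
        if fr < 0 or fs < 0 or fr + fs >= 1:
            raise ValueError("noise fractions must be >= 0 and sum < 1")
        if self.quant_method not in ("srtm", "logan", "mrtm2"):
            raise ValueError(f"unknown quant method {self.quant_method}")
        if self.stat_test not in ("t", "perm"):
            raise ValueError("stat_test must be 't' or 'perm'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.framing()  # raises on a bad scheme
        ReconConfig(self.recon_iterations, self.recon_psf_fwhm_mm)

    def framing(self) -> Framing:
        return make_framing(self.framing_scheme)

    def scanner(self) -> ScannerModel:
        return ScannerModel.for_image(
            self.grid_shape, self.voxel_size_mm,
            n_angles=self.n_angles, psf_fwhm_mm=self.acquisition_psf_fwhm_mm,
        )

    def recon_config(self) -> ReconConfig:
        return ReconConfig(self.recon_iterations, self.recon_psf_fwhm_mm)

    def resolve_counts(self, brain_volume_mm3: float) -> float:
        if self.total_counts == "match_density":
            return 3e8 * brain_volume_mm3 / PAPER_BRAIN_VOLUME_MM3
        return float(self.total_counts)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["framing_scheme"] = [list(x) for x in self.framing_scheme]
        for key in ("roi_sizes_mm3", "roi_deltas", "roi_baseline_bp"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ChallengeConfig":
        d = dict(d)
        for key in ("grid_shape", "roi_sizes_mm3", "roi_deltas", "roi_baseline_bp"):
            if key in d:
                d[key] = tuple(d[key])
        if "framing_scheme" in d:
            d["framing_scheme"] = tuple(tuple(x) for x in d["framing_scheme"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ChallengeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def desk_small(cls, seed: int = 0, **overrides) -> "ChallengeConfig":
        """A small, fast configuration preserving the study design.

        32x32x22 grid at 3 mm, count budget matched to the full-scale
        per-volume density, 30 MLEM iterations -- one full 5-subject
        challenge replicate runs in about a minute.
        """
        kwargs = dict(
            grid_shape=(32, 32, 22),
            voxel_size_mm=3.0,
            total_counts="match_density",
            recon_iterations=30,
            seed=seed,
        )
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
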