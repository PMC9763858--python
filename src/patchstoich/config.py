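"""Run configuration.

A single :class:`RunConfig` carries every tunable parameter of the pipeline.
Defaults are the instrument/analysis constants used throughout: 8 px detection
radius, 17 px background box, 75-100 % linking overlap, 50-200 % intensity
ratio, 5 extrapolation frames, 10-frame stoichiometry gate, 0.6-molecule
stoichiometry kernel, 0.001 gradient kernel, 25 px local-Otsu radius, 180 nm
density kernel, 53 nm pixels.  The SNR definition and threshold have no
published values; the default matched-filter threshold (8.0) was calibrated
with :func:`patchstoich.detect.calibrate_snr_threshold` on blank synthetic
frames so that fewer than one false positive survives per 100 frames
(see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.354820045030949


@dataclass
class RunConfig:
    # --- geometry / acquisition -------------------------------------------
    pixel_size_nm: float = 53.0
    frame_interval_s: float = 1.0 / 77.0
    psf_fwhm_nm: float = 180.0

    # --- spot detection ----------------------------------------------------
    detect_radius_px: int = 8
    bg_box_px: int = 17
    snr_method: str = "matched"   # or "disk_sum"
    snr_threshold: float = 8.0
    prefilter_sigma: float = 3.0     # cheap peak-height cut before mask fitting
    mask_fit_tol_px: float = 0.01
    mask_fit_max_iter: int = 50

    # --- track linking -----------------------------------------------------
    link_overlap_bounds: tuple[float, float] = (0.75, 1.00)
    link_ratio_bounds: tuple[float, float] = (0.50, 2.00)

    # --- stoichiometry -----------------------------------------------------
    n_extrapolation_frames: int = 5
    max_start_frame: int = 10
    stoich_kernel_width: float = 0.6       # molecules (Gaussian sd)
    periodicity_min_interval: float | None = None  # None -> kernel width
    ck_window: int = 5
    ck_exponent: float = 2.0
    min_step_fraction: float = 0.5         # of the I_1 estimate
    postbleach_fraction: float = 0.25      # "sufficient photobleaching" knee

    # --- clustering --------------------------------------------------------
    otsu_local_radius_px: int = 25
    min_object_px: int = 4
    density_kernel_width_nm: float = 180.0
    gradient_kernel_width: float = 0.001   # dimensionless dH/dr
    ripley_step_nm: float = 20.0
    ripley_max_um: float = 10.0
    edge_correction: str = "isotropic"     # or "none"

    # --- statistics --------------------------------------------------------
    family_alpha: float = 0.05
    n_tests: int = 5
    stoich_split: float = 15.0

    # --- bookkeeping -------------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "frame_interval_s", "psf_fwhm_nm",
                     "stoich_kernel_width", "gradient_kernel_width",
                     "density_kernel_width_nm", "ripley_step_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("detect_radius_px", "bg_box_px", "otsu_local_radius_px"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("link_overlap_bounds", "link_ratio_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must be an ordered pair")

    # -----------------------------------------------------------------
    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm / FWHM_TO_SIGMA / self.pixel_size_nm

    @property
    def psf_fwhm_px(self) -> float:
        return self.psf_fwhm_nm / self.pixel_size_nm

    @property
    def min_interval(self) -> float:
        """Smallest stoichiometry interval entering the periodicity KDE."""
        if self.periodicity_min_interval is None:
            return self.stoich_kernel_width
        return self.periodicity_min_interval

    # -----------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["link_overlap_bounds"] = list(d["link_overlap_bounds"])
        d["link_ratio_bounds"] = list(d["link_ratio_bounds"])
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration, stamped into every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for name in ("link_overlap_bounds", "link_ratio_bounds"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)
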