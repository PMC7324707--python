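"""Aggregated configuration for the full fusion pipeline.

The published method leaves many parameters open (saliency threshold
method, structure-tensor weight and smoothing scale, fidelity weight,
step sizes, stopping rule); :class:`FusionConfig` gathers every free
parameter with the package defaults, validates them against the module
contracts before any computation starts, and can be loaded from a flat
``key = value`` config file with CLI-flag precedence on top.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

from .errors import ValidationError
from .variational import SolverConfig

__all__ = ["FusionConfig", "load_config"]


@dataclass(frozen=True)
class FusionConfig:
    """Every tunable of the two-stage pipeline, with validated defaults."""

    # stage 1: saliency
    levels: int = 256
    threshold_method: str = "otsu"
    threshold_fraction: float = 0.5
    # stage 1: structure tensor
    alpha_st: float = 0.5
    rho: float = 1.0
    # stage 1: weights
    weight_mode: str = "symmetric"
    eps: float = 1e-12
    # stage 2: solver
    alpha_fid: float = 8.0
    sigma: float = 0.35
    tau: float = 0.35
    max_iter: int = 300
    tol: float = 1e-5
    # metrics
    mi_bins: int = 256
    qw_window: int = 7
    # plumbing
    verbosity: int = 0
    debug_dir: str | None = None

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            alpha_fid=self.alpha_fid,
            sigma=self.sigma,
            tau=self.tau,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def validate(self) -> "FusionConfig":
        if self.levels < 2:
            raise ValidationError(f"levels must be >= 2, got {self.levels}")
        if self.threshold_method not in ("otsu", "fraction"):
            raise ValidationError(
                f"threshold_method must be 'otsu' or 'fraction', "
                f"got {self.threshold_method!r}"
            )
        if self.threshold_method == "fraction" and not (
            0.0 < self.threshold_fraction < 1.0
        ):
            raise ValidationError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.alpha_st < 0:
            raise ValidationError(f"alpha_st must be >= 0, got {self.alpha_st}")
        if self.rho < 0:
            raise ValidationError(f"rho must be >= 0, got {self.rho}")
        if self.weight_mode not in ("symmetric", "literal"):
            raise ValidationError(
                f"weight_mode must be 'symmetric' or 'literal', "
                f"got {self.weight_mode!r}"
            )
        if self.mi_bins < 2:
            raise ValidationError(f"mi_bins must be >= 2, got {self.mi_bins}")
        if self.qw_window < 3 or self.qw_window % 2 == 0:
            raise ValidationError(
                f"qw_window must be odd and >= 3, got {self.qw_window}"
            )
        self.solver_config().validate()
        return self

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(FusionConfig)}


def _coerce(key: str, raw: str):
    """Parse a raw string value to the declared type of a config field."""
    target = _FIELD_TYPES[key]
    if key == "debug_dir":
        return None if raw.lower() in ("none", "") else raw
    if target == "int":
        return int(raw)
    if target == "float":
        return float(raw)
    return raw


def load_config(
    path: str | os.PathLike | None = None, overrides: dict | None = None
) -> FusionConfig:
    """Build a validated config: defaults < config file < overrides.

    The file format is flat ``key = value`` lines; blank lines and lines
    starting with ``#`` are ignored.  Unknown keys (in the file or the
    overrides) are hard errors naming the key.
    """
    values: dict = {}
    if path is not None:
        with open(os.fspath(path)) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'key = value', got {line!r}"
                    )
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in _FIELD_TYPES:
                    raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
                values[key] = _coerce(key, raw.strip())
    for key, value in (overrides or {}).items():
        if key not in _FIELD_TYPES:
            raise ValidationError(f"unknown config key {key!r}")
        if value is not None:
            values[key] = value
    return FusionConfig(**values).validate()
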