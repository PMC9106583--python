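"""Run configuration shared by the pipeline and the command-line interface."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters.

    ``window_plot`` is the charge-plot window (residues); ``window_block``
    the block-designation window; ``block_area_threshold`` the designation
    threshold in windowed-sum plot-area units; ``neutral_band`` the
    |delta B_LC| below which a protein counts as unaffected by
    phosphorylation.
    """

    window_plot: int = 25
    window_block: int = 35
    block_area_threshold: float = 20.0
    phospho_charge: int = -2
    kappa_blob: int = 5
    neutral_band: float = 1.0
    seed: int = 0
    output_dir: str = "chargeblocks_out"

    def __post_init__(self) -> None:
        for name in ("window_plot", "window_block"):
            w = getattr(self, name)
            if w <= 0 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        if self.block_area_threshold <= 0:
            raise ValueError("block_area_threshold must be > 0")
        if self.kappa_blob < 2:
            raise ValueError("kappa_blob must be >= 2")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a TOML file; keyword overrides win over file values."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
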