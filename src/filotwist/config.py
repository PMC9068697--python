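"""Default parameters and run configuration.

Every analysis default lives here so it can be overridden from the CLI
and serialized alongside outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .helix import ACTIN, COFILACTIN, HelicalParams

#: Lattice presets measured on the two bundle types: fascin-linked
#: F-actin bundles pack at 12.3 nm, pure cofilactin bundles at 11.5 nm
#: with every other column rolled 90 deg.
BUNDLE_PRESETS: dict[str, dict] = {
    "fascin": {
        "params": ACTIN,
        "lattice_constant": 12.3,
        "alternation": "none",
    },
    "cofilactin": {
        "params": COFILACTIN,
        "lattice_constant": 11.5,
        "alternation": "column_roll_90",
    },
}


@dataclass
class RunConfig:
    """Parameter tree for a pipeline run; serialized next to outputs."""

    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    # synthetic tomogram defaults
    voxel_size_nm: float = 1.0
    blob_sigma_nm: float = 2.0
    padding_nm: float = 8.0
    snr: float | None = None
    wedge_halfangle_deg: float | None = None
    bundle_preset: str = "cofilactin"
    n_rings: int = 1
    bundle_length_nm: float = 150.0

    # tomographic analysis defaults
    min_separation_nm: float = 8.0
    resample_spacing_nm: float = 1.0
    outlier_k: float = 3.0
    pitch_range_nm: tuple[float, float] = (15.0, 60.0)
    cofilactin_max_nm: float = 31.0
    actin_min_nm: float = 33.0

    # fluorescence defaults
    mip_window: int = 40
    transition_level: float = 0.5
    pixel_size_um: float = 0.05

    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("pitch_range_nm"):
            d["pitch_range_nm"] = tuple(d["pitch_range_nm"])
        return cls(**d)

    def bundle_params(self) -> tuple[HelicalParams, float, str]:
        p = BUNDLE_PRESETS[self.bundle_preset]
        return p["params"], p["lattice_constant"], p["alternation"]
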