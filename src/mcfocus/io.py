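"""Result readers/writers and run configuration.

All artifacts are plain text: CSV tables for grids, profiles and exit
records (numbers serialized with 17 significant digits so round-trips are
exact) and JSON for the weight ledger and run summaries. Every writer adds
the generating config hash so a result can be traced to its exact inputs;
identical config + seed reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .transport import FluenceGrid, TransportResult

__all__ = [
    "RunConfig",
    "config_hash",
    "write_ledger",
    "read_ledger",
    "write_grid",
    "read_grid",
    "write_profile",
    "read_profile",
    "write_exit_records",
    "read_exit_records",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one CLI run."""

    subcommand: str
    stack: str = "mousehead_785"
    n_photons: int = 1_000_000
    seed: int = 0
    mode: str = "fresnel_full"
    roulette_threshold: float = 1e-4
    roulette_m: float = 10.0
    depths_mm: tuple[float, ...] = (0.4, 0.8, 1.4, 2.0)
    bin_width_mm: float = 0.05
    half_angle_deg: float | None = 15.0
    na: float = 0.25
    emission_model: str = "forward"
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths_mm"] = list(self.depths_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["depths_mm"] = tuple(d.get("depths_mm", (0.4, 0.8, 1.4, 2.0)))
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a run configuration. Wall-clock and the output
    location are excluded so reruns into different directories still
    produce identical artifacts."""
    d = config.to_dict()
    d.pop("out_dir", None)
    canon = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sidecar(path: Path, config: RunConfig | None) -> dict:
    meta = {"format_version": 1}
    if config is not None:
        meta["config"] = config.to_dict()
        meta["config_hash"] = config_hash(config)
    return meta


def write_ledger(result: TransportResult, path: str | Path,
                 config: RunConfig | None = None) -> None:
    """Weight ledger as JSON, with the conservation error it must satisfy."""
    doc = _sidecar(Path(path), config)
    doc["ledger"] = {k: float(v) for k, v in result.ledger.items()}
    doc["n_photons"] = result.n_photons
    doc["initial_weight"] = result.initial_weight
    doc["seed"] = result.seed
    doc["mode"] = result.mode
    doc["conservation_error"] = result.conservation_error()
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ledger(path: str | Path, check: bool = True) -> dict:
    """Read a ledger JSON; re-validates weight conservation by default."""
    doc = json.loads(Path(path).read_text())
    led = doc["ledger"]
    if check:
        total = (
            led["specular"] + led["absorbed"] + led["overflow"]
            + led["escaped_top"] + led["transmitted_bottom"]
            + led["roulette_net"] + led["boundary_lost"]
        )
        launched = doc["n_photons"] * doc["initial_weight"]
        if abs(total - launched) > 1e-6 * launched:
            raise ValueError(f"{path}: ledger violates weight conservation")
    return doc


def write_grid(grid: FluenceGrid, path: str | Path,
               config: RunConfig | None = None) -> None:
    """Fluence grid as CSV: one row per (r, z) cell with bin edges, raw
    absorbed weight and the normalized fluence."""
    f = grid.fluence()
    re, ze = grid.r_edges, grid.z_edges
    ir, iz = np.meshgrid(np.arange(grid.nr), np.arange(grid.nz), indexing="ij")
    df = pd.DataFrame(
        {
            "r_lo": re[:-1][ir.ravel()],
            "r_hi": re[1:][ir.ravel()],
            "z_lo": ze[:-1][iz.ravel()],
            "z_hi": ze[1:][iz.ravel()],
            "absorbed_weight": grid.A.ravel(),
            "fluence": f.ravel(),
        }
    )
    header = _grid_header(grid, config)
    with Path(path).open("w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _grid_header(grid: FluenceGrid, config: RunConfig | None) -> str:
    meta = {
        "dr": grid.dr, "dz": grid.dz, "nr": grid.nr, "nz": grid.nz,
        "z0": grid.z0, "overflow": grid.overflow,
        "n_launched": grid.n_launched,
        "normalization_mode": grid.normalization_mode,
    }
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return "# mcfocus-grid " + json.dumps(meta, sort_keys=True) + "\n"


def read_grid(path: str | Path) -> FluenceGrid:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# mcfocus-grid "):
            raise ValueError(f"{path}: not a fluence-grid CSV")
        meta = json.loads(header[len("# mcfocus-grid "):])
        df = pd.read_csv(fh, float_precision="round_trip")
    grid = FluenceGrid(
        dr=meta["dr"], dz=meta["dz"], nr=meta["nr"], nz=meta["nz"],
        z0=meta["z0"], normalization_mode=meta["normalization_mode"],
    )
    grid.A = df["absorbed_weight"].to_numpy().reshape(meta["nr"], meta["nz"])
    grid.overflow = meta["overflow"]
    grid.n_launched = meta["n_launched"]
    return grid


def write_profile(profile: pd.DataFrame, path: str | Path,
                  config: RunConfig | None = None) -> None:
    """Radial emission profile CSV (zero bins preserved, not dropped)."""
    with Path(path).open("w") as fh:
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        profile.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_exit_records(emission, path: str | Path,
                       config: RunConfig | None = None) -> None:
    """Top-surface exit records as CSV (exit_r_mm, exit_angle_deg, weight)."""
    df = pd.DataFrame(
        {
            "exit_r_mm": emission.exit_r * 10.0,
            "exit_angle_deg": emission.exit_angle_deg,
            "weight": emission.exit_w,
        }
    )
    with Path(path).open("w") as fh:
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_exit_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
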