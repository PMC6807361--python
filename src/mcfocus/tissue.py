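"""Layered mouse-head tissue stacks and their optical properties.

The geometry is a plane-parallel stack with ``z = 0`` at the scalp (skin)
surface and z increasing downward, in cm. The bundled presets encode the
published optical parameters of a hairless-mouse head (scalp/skin, skull,
cerebrospinal fluid, cortex) at the 785 nm excitation and 1100 nm emission
wavelengths; the emission stack carries a thin air layer above the skin at
z in [-0.01, 0] cm. The cortex is modeled as an effectively semi-infinite
substrate (1 cm thick, photons crossing its bottom are terminated as
transmitted); quantum-dot planes sit at depths 0.4/0.8/1.4/2.0 mm below
the scalp surface, i.e. 0/0.4/1.0/1.6 mm of cortex path below the cortical
surface at 0.4 mm.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LayerOpticalProperties",
    "LayerStack",
    "default_stack",
    "load_stack",
    "save_stack",
    "layer_at_depth",
    "QD_DEPTHS_CM",
    "CORTEX_SUBSTRATE_CM",
    "EXCITATION_785",
    "EMISSION_1100",
]

EXCITATION_785 = "excitation_785"
EMISSION_1100 = "emission_1100"

#: quantum-dot plane depths below the scalp surface (cm): 0.4/0.8/1.4/2.0 mm
QD_DEPTHS_CM = (0.04, 0.08, 0.14, 0.20)

#: cortex substrate thickness (cm) standing in for a semi-infinite medium
CORTEX_SUBSTRATE_CM = 1.0

#: depth of the cortical surface below the scalp (skin + skull + CSF)
CORTICAL_SURFACE_CM = 0.04


@dataclass(frozen=True)
class LayerOpticalProperties:
    """One homogeneous tissue layer.

    Parameters are the usual tissue-optics set: refractive index ``n``,
    absorption ``mu_a`` and scattering ``mu_s`` coefficients (cm^-1),
    scattering anisotropy ``g`` (mean single-scattering cosine) and the
    layer ``thickness`` in cm (``math.inf`` allowed for the bottom layer).
    """

    name: str
    n: float
    mu_a: float
    mu_s: float
    g: float
    thickness: float

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError(f"layer {self.name!r}: refractive index n must be >= 1")
        if self.mu_a < 0.0 or self.mu_s < 0.0:
            raise ValueError(f"layer {self.name!r}: mu_a and mu_s must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"layer {self.name!r}: anisotropy g must be in [-1, 1]")
        if not (self.thickness > 0.0):
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (cm^-1)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class LayerStack:
    """An ordered top-to-bottom stack of layers with derived z boundaries.

    ``z_top`` is the z coordinate of the top surface (0 unless an air guard
    layer sits above the skin, in which case it is negative so that the skin
    surface stays at z = 0). ``ambient_above_n`` is the refractive index of
    the detection medium above the stack.
    """

    wavelength_tag: str
    layers: tuple[LayerOpticalProperties, ...]
    ambient_above_n: float = 1.0
    z_top: float = 0.0
    z_boundaries: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if self.ambient_above_n < 1.0:
            raise ValueError("ambient refractive index must be >= 1")
        z = [self.z_top]
        for lay in self.layers:
            if math.isinf(lay.thickness) and lay is not self.layers[-1]:
                raise ValueError("only the bottom layer may be infinite")
            z.append(z[-1] + lay.thickness)
        if any(b - a <= 0 for a, b in zip(z, z[1:])):
            raise ValueError("z boundaries must be strictly increasing")
        object.__setattr__(self, "z_boundaries", tuple(z))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def z_bottom(self) -> float:
        return self.z_boundaries[-1]

    def arrays(self) -> dict[str, np.ndarray]:
        """Per-layer property arrays for the compiled transport kernel."""
        return {
            "n": np.array([l.n for l in self.layers]),
            "mu_a": np.array([l.mu_a for l in self.layers]),
            "mu_s": np.array([l.mu_s for l in self.layers]),
            "g": np.array([l.g for l in self.layers]),
            "zb": np.array(self.z_boundaries),
        }

    def layer_named(self, name: str) -> LayerOpticalProperties:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)


# Published optical parameters of the hairless-mouse head, per wavelength:
# (name, n, mu_a [cm^-1], mu_s [cm^-1], g, thickness [cm]).
_TABLE_785 = (
    ("skin", 1.37, 1.62, 238.9, 0.9, 0.02),
    ("skull", 1.454, 0.087, 162.7, 0.9, 0.01),
    ("csf", 1.33, 0.1, 0.0, 1.0, 0.01),
    ("cortex", 1.368, 0.087, 76.2, 0.9, CORTEX_SUBSTRATE_CM),
)
_TABLE_1100 = (
    ("air", 1.0, 0.001, 0.0, 1.0, 0.01),
    ("skin", 1.37, 0.35, 171.5, 0.9, 0.02),
    ("skull", 1.45, 0.4, 135.6, 0.9, 0.01),
    ("csf", 1.33, 1.0, 0.0, 1.0, 0.01),
    ("cortex", 1.368, 0.5, 71.4, 0.9, CORTEX_SUBSTRATE_CM),
)

_PRESET_NAMES = {
    EXCITATION_785: "mousehead_785",
    EMISSION_1100: "mousehead_1100",
}


def default_stack(wavelength_tag: str, cortex_thickness: float = 0.0) -> LayerStack:
    """Build the preset mouse-head stack for one wavelength.

    ``cortex_thickness`` (cm) is the cortex path length from the cortical
    surface down to the quantum-dot plane (0 puts the plane on the cortical
    surface); it selects a QD depth but does not shrink the cortex layer,
    which is always the semi-infinite substrate. Use :func:`qd_depth` to
    convert it to an absolute depth.
    """
    if cortex_thickness < 0.0:
        raise ValueError("cortex_thickness must be >= 0")
    if wavelength_tag == EXCITATION_785:
        table, z_top = _TABLE_785, 0.0
    elif wavelength_tag == EMISSION_1100:
        table, z_top = _TABLE_1100, -0.01
    else:
        raise ValueError(f"unknown wavelength tag {wavelength_tag!r}")
    layers = tuple(LayerOpticalProperties(*row) for row in table)
    return LayerStack(wavelength_tag=wavelength_tag, layers=layers, z_top=z_top)


def qd_depth(cortex_thickness: float) -> float:
    """Absolute quantum-dot depth (cm) below the scalp surface for a given
    cortex path length (cm) below the cortical surface."""
    if cortex_thickness < 0.0:
        raise ValueError("cortex_thickness must be >= 0")
    return CORTICAL_SURFACE_CM + cortex_thickness


def layer_at_depth(stack: LayerStack, z: float) -> int:
    """Index of the layer containing depth ``z`` (cm). A point exactly on an
    interior boundary belongs to the layer below (z-increasing convention)."""
    zb = stack.z_boundaries
    if z < zb[0] or z >= zb[-1]:
        raise ValueError(f"z={z} outside stack span [{zb[0]}, {zb[-1]})")
    # rightmost boundary <= z gives the layer below an exact boundary hit
    return min(bisect_right(zb, z) - 1, stack.n_layers - 1)


def _scale_length(value: float, scale: float) -> float:
    # decimal re-rounding keeps cm <-> mm conversion an exact round trip
    # for table-precision inputs (cm values pass through untouched)
    return value if scale == 1.0 else round(value * scale, 12)


def _stack_to_dict(stack: LayerStack, units: str = "cm") -> dict:
    scale = 10.0 if units == "mm" else 1.0
    return {
        "wavelength_tag": stack.wavelength_tag,
        "units": units,
        "ambient_above_n": stack.ambient_above_n,
        "z_top": _scale_length(stack.z_top, scale),
        "layers": [
            {
                "name": l.name,
                "n": l.n,
                "mu_a": l.mu_a,
                "mu_s": l.mu_s,
                "g": l.g,
                "thickness": (
                    "infinite"
                    if math.isinf(l.thickness)
                    else _scale_length(l.thickness, scale)
                ),
            }
            for l in stack.layers
        ],
    }


def _stack_from_dict(doc: dict) -> LayerStack:
    try:
        units = doc.get("units", "cm")
        if units not in ("cm", "mm"):
            raise ValueError(f"units must be 'cm' or 'mm', got {units!r}")
        scale = 0.1 if units == "mm" else 1.0
        layers = []
        for entry in doc["layers"]:
            th = entry["thickness"]
            th = (
                math.inf
                if th == "infinite"
                else _scale_length(float(th), scale)
            )
            layers.append(
                LayerOpticalProperties(
                    name=str(entry["name"]),
                    n=float(entry["n"]),
                    mu_a=float(entry["mu_a"]),
                    mu_s=float(entry["mu_s"]),
                    g=float(entry["g"]),
                    thickness=th,
                )
            )
        return LayerStack(
            wavelength_tag=str(doc.get("wavelength_tag", "custom")),
            layers=tuple(layers),
            ambient_above_n=float(doc.get("ambient_above_n", 1.0)),
            z_top=_scale_length(float(doc.get("z_top", 0.0)), scale),
        )
    except KeyError as exc:
        raise ValueError(f"stack config missing required key: {exc}") from exc


def load_stack(config_path: str | Path) -> LayerStack:
    """Load and validate a layer stack from a YAML config (units key chooses
    mm or cm; mm values are converted to cm internally)."""
    path = Path(config_path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: stack config must be a mapping")
    return _stack_from_dict(doc)


def save_stack(stack: LayerStack, config_path: str | Path, units: str = "cm") -> None:
    """Write a stack to YAML; ``load_stack`` round-trips it exactly."""
    if units not in ("cm", "mm"):
        raise ValueError("units must be 'cm' or 'mm'")
    with Path(config_path).open("w") as fh:
        yaml.safe_dump(_stack_to_dict(stack, units=units), fh, sort_keys=False)


def preset_path(name: str) -> Path:
    """Filesystem path of a bundled preset config (``mousehead_785`` or
    ``mousehead_1100``)."""
    ref = resources.files("mcfocus") / "presets" / f"{name}.yaml"
    return Path(str(ref))


def stack_from_preset(name: str) -> LayerStack:
    """Resolve a preset name or a config path to a stack."""
    for tag, preset in _PRESET_NAMES.items():
        if name in (preset, tag):
            return default_stack(tag)
    p = Path(name)
    if p.exists():
        return load_stack(p)
    raise ValueError(f"unknown preset or missing config file: {name!r}")
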