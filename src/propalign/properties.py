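"""Amino-acid property scales, weights, and the property-file format.

A protein residue is represented not by its letter but by a vector of
biochemical property values (hydrophobicity, size, coil propensity, ...).
Each property is a :class:`PropertyScale` mapping the 20 standard amino
acids to real numbers; a :class:`WeightedPropertySet` bundles several
scales with nonnegative weights summing to 1, and is the scoring model of
the property-profile aligner.

Scales are min-max normalized to [0, 1] by default so that differently
scaled properties are commensurable before weighting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

#: The 20 standard amino acids in the canonical order of the property-file
#: format (line 2 of the file must list exactly these letters in this order).
ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

WEIGHT_TOL = 1e-9


class PropertyFormatError(ValueError):
    """Raised when a property file does not follow the expected grammar."""


@dataclass(frozen=True)
class PropertyScale:
    """A named numeric scale over the 20 standard amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.values)
        extra = set(self.values) - set(ALPHABET)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def as_array(self) -> np.ndarray:
        """Values as a length-20 float array in canonical alphabet order."""
        return np.array([self.values[aa] for aa in ALPHABET], dtype=float)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def normalize_scale(scale: PropertyScale) -> PropertyScale:
    """Min-max normalize a scale to [0, 1].

    Returns a new scale with ``np(x) = (p(x) - min) / (max - min)``; the
    minimum maps to 0 and the maximum to 1.  Idempotent on already
    normalized scales.

    Raises
    ------
    ValueError
        If the scale is constant (max == min), which cannot be normalized.
    """
    vals = scale.as_array()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError(
            f"scale {scale.name!r} is constant ({lo}); min-max normalization "
            "is undefined for a degenerate property"
        )
    return PropertyScale(
        scale.name, {aa: (scale.values[aa] - lo) / (hi - lo) for aa in ALPHABET}
    )


@dataclass(frozen=True)
class WeightedPropertySet:
    """An ordered set of property scales with weights summing to 1.

    Parameters
    ----------
    scales:
        One or more :class:`PropertyScale` (k >= 1).
    weights:
        Nonnegative weight per scale; must sum to 1 within 1e-9.
    normalized:
        Whether min-max normalization has been applied to every scale.
    """

    scales: tuple[PropertyScale, ...]
    weights: tuple[float, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(self.scales))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.scales) < 1:
            raise ValueError("a property set needs at least one scale")
        if len(self.weights) != len(self.scales):
            raise ValueError("one weight per scale is required")
        if any(w < 0 for w in self.weights):
            raise ValueError(f"weights must be nonnegative, got {self.weights}")
        total = math.fsum(self.weights)
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(
                f"property weights must sum to 1.0 (got {total!r}); "
                "renormalize or fix the weights"
            )

    @property
    def k(self) -> int:
        return len(self.scales)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scales)

    def normalize(self) -> "WeightedPropertySet":
        """Return the set with every scale min-max normalized to [0, 1]."""
        if self.normalized:
            return self
        return WeightedPropertySet(
            tuple(normalize_scale(s) for s in self.scales), self.weights, True
        )

    def with_weights(self, weights: Sequence[float]) -> "WeightedPropertySet":
        """Same scales, different weights (used by the grid search)."""
        return replace(self, weights=tuple(float(w) for w in weights))

    def value_matrix(self) -> np.ndarray:
        """(k, 20) array of property values in alphabet order."""
        return np.stack([s.as_array() for s in self.scales])

    def distance_matrix(self) -> np.ndarray:
        """20x20 weighted-L1 distance between every residue pair.

        ``D[a, b] = sum_k w_k * |p_k(a) - p_k(b)|`` on the current (raw or
        normalized) scale values.
        """
        vals = self.value_matrix()  # (k, 20)
        diffs = np.abs(vals[:, :, None] - vals[:, None, :])  # (k, 20, 20)
        w = np.asarray(self.weights)
        return np.tensordot(w, diffs, axes=1)


# ---------------------------------------------------------------------------
# property-file format
# ---------------------------------------------------------------------------
#
# Line 1: free-text header (content ignored).
# Line 2: "A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V" (whitespace tolerated
#         around commas).
# Then, per property:
#   "#PROPERTY <name>"
#   20 comma-delimited numbers, one per residue in alphabet order
#   "W:<weight>"
# Blank lines between blocks and \r\n endings are tolerated.


def parse_property_file(text: str, *, weight_policy: str = "reject") -> WeightedPropertySet:
    """Parse the comma-delimited property-file format.

    Parameters
    ----------
    text:
        File content.
    weight_policy:
        ``"reject"`` (default) raises if the weights do not sum to 1 within
        1e-9; ``"renormalize"`` divides them by their sum instead.
    """
    if weight_policy not in ("reject", "renormalize"):
        raise ValueError(f"unknown weight_policy {weight_policy!r}")
    lines = [ln.strip() for ln in text.splitlines()]
    # drop trailing blank-only content but keep internal structure
    nonblank = [(i, ln) for i, ln in enumerate(lines) if ln]
    if len(nonblank) < 2:
        raise PropertyFormatError("property file must have a header line and an alphabet line")
    # header = nonblank[0] (content ignored)
    alpha_lineno, alpha_line = nonblank[1]
    letters = [f.strip().upper() for f in alpha_line.split(",")]
    if letters != list(ALPHABET):
        raise PropertyFormatError(
            f"line {alpha_lineno + 1}: alphabet line must be the 20 standard "
            f"letters in canonical order {','.join(ALPHABET)}; got {alpha_line!r}"
        )

    scales: list[PropertyScale] = []
    weights: list[float] = []
    rest = nonblank[2:]
    pos = 0
    while pos < len(rest):
        lineno, line = rest[pos]
        if not line.startswith("#PROPERTY"):
            raise PropertyFormatError(
                f"line {lineno + 1}: expected '#PROPERTY <name>', got {line!r}"
            )
        name = line[len("#PROPERTY"):].strip()
        if not name:
            raise PropertyFormatError(f"line {lineno + 1}: property name is empty")
        if pos + 1 >= len(rest):
            raise PropertyFormatError(f"property {name!r} is missing its value line")
        val_lineno, val_line = rest[pos + 1]
        fields = [f.strip() for f in val_line.split(",")]
        if len(fields) != 20:
            raise PropertyFormatError(
                f"line {val_lineno + 1}: property {name!r} has {len(fields)} "
                "values, expected 20"
            )
        try:
            nums = [float(f) for f in fields]
        except ValueError as exc:
            raise PropertyFormatError(
                f"line {val_lineno + 1}: non-numeric value in property {name!r}: {exc}"
            ) from None
        if pos + 2 >= len(rest):
            raise PropertyFormatError(f"property {name!r} is missing its 'W:' weight line")
        w_lineno, w_line = rest[pos + 2]
        if not w_line.upper().startswith("W:"):
            raise PropertyFormatError(
                f"line {w_lineno + 1}: expected 'W:<weight>' for property "
                f"{name!r}, got {w_line!r}"
            )
        try:
            weight = float(w_line[2:].strip())
        except ValueError:
            raise PropertyFormatError(
                f"line {w_lineno + 1}: non-numeric weight for property {name!r}"
            ) from None
        scales.append(PropertyScale(name, dict(zip(ALPHABET, nums))))
        weights.append(weight)
        pos += 3

    if not scales:
        raise PropertyFormatError("property file defines no '#PROPERTY' blocks")
    total = math.fsum(weights)
    if abs(total - 1.0) > WEIGHT_TOL:
        if weight_policy == "renormalize":
            weights = [w / total for w in weights]
        else:
            raise PropertyFormatError(
                f"property weights sum to {total!r}, not 1.0; pass "
                "weight_policy='renormalize' to rescale them"
            )
    return WeightedPropertySet(tuple(scales), tuple(weights))


def write_property_file(props: WeightedPropertySet, *, header: str = "Amino acid property file") -> str:
    """Serialize a property set; round-trips exactly through the parser."""
    out = [header, ",".join(ALPHABET)]
    for scale, weight in zip(props.scales, props.weights):
        out.append(f"#PROPERTY {scale.name}")
        out.append(",".join(repr(scale.values[aa]) for aa in ALPHABET))
        out.append(f"W:{weight!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# shipped presets: identity-range-optimized weights and gap penalties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    """Optimized weights and gap penalties for one percent-identity range.

    Weights are in the fixed order (hydrophobicity, size, coil propensity,
    thiol group); ``alpha``/``beta`` are gap initiation/extension penalties
    in distance units.
    """

    identity_low: float
    identity_high: float
    weights: tuple[float, float, float, float]
    alpha: float
    beta: float
    n_pairs: int
    label: str = field(default="")

    def __post_init__(self) -> None:
        if abs(math.fsum(self.weights) - 1.0) > WEIGHT_TOL:
            raise ValueError(f"preset {self.label!r} weights do not sum to 1")


def _load_presets() -> tuple[Preset, ...]:
    raw = json.loads(
        resources.files("propalign.data").joinpath("presets.json").read_text()
    )
    return tuple(
        Preset(
            identity_low=row["identity_low"],
            identity_high=row["identity_high"],
            weights=tuple(row["weights"]),
            alpha=row["alpha"],
            beta=row["beta"],
            n_pairs=row["n_pairs"],
            label=row["label"],
        )
        for row in raw["presets"]
    )


#: Shipped identity-range presets, low range first. Intervals are half-open
#: [low, high) except the last, which includes 100.
PRESETS: tuple[Preset, ...] = _load_presets()

#: The preset applied when no identity estimate is available (30-40% range).
DEFAULT_PRESET: Preset = next(p for p in PRESETS if p.label == "30-40%")


def select_preset(percent_identity: float) -> Preset:
    """Pick the shipped preset whose identity range contains the value.

    Ranges are half-open ``[low, high)``; a boundary value such as 40 falls
    in the higher range.  The final range includes 100.
    """
    if not 0.0 <= percent_identity <= 100.0:
        raise ValueError(f"percent identity must be in [0, 100], got {percent_identity}")
    for preset in PRESETS:
        if preset.identity_low <= percent_identity < preset.identity_high:
            return preset
    if percent_identity == 100.0:
        return PRESETS[-1]
    raise AssertionError("presets do not cover [0, 100]")  # pragma: no cover


def load_example_properties() -> WeightedPropertySet:
    """The two-property (hydrophobicity 0.6 / size 0.4) demonstration set."""
    text = resources.files("propalign.data").joinpath("example_properties.txt").read_text()
    return parse_property_file(text)


def load_default_properties(preset: Preset | None = None) -> WeightedPropertySet:
    """The bundled four-property default set, weighted per a preset.

    Scale values are implementer-sourced from standard literature scales
    (Kyte-Doolittle hydropathy, Zamyatnin residue volumes, a coil
    conformational parameter, binary thiol indicator); supply your own
    property file if you need a specific published scale.
    """
    text = resources.files("propalign.data").joinpath("default_properties.txt").read_text()
    props = parse_property_file(text)
    if preset is not None:
        props = props.with_weights(preset.weights)
    return props
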