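"""Dinucleotide helical parameter sets.

A :class:`HelicalParameterSet` holds the six rigid-body base-step parameters
(Shift, Slide, Rise / Tilt, Roll, Twist) for each of the 16 dinucleotide
steps, and the six intra-pair parameters (Shear, Stretch, Stagger / Buckle,
Propeller, Opening) for the four Watson-Crick base pairs.  Translations are
in Å, angles in degrees as tabulated; conversion to radians happens in the
frame-propagation code.

Set ``"i"`` (experimental/crystallographic compilation) ships with the
package.  Sets ``"ii"`` and ``"iii"`` are recognized labels but their values
are not bundled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEP_FIELDS = ("shift", "slide", "rise", "tilt", "roll", "twist")
PAIR_FIELDS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")

KNOWN_LABELS = ("i", "ii", "iii")
_BUNDLED = {"i": "helical_params_i.tsv"}


@dataclass(frozen=True)
class StepParameters:
    """Six rigid-body parameters of one dinucleotide step (Å / degrees)."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def translation(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise])


@dataclass(frozen=True)
class PairParameters:
    """Six intra-base-pair parameters (Å / degrees)."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def translation(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger])


@dataclass(frozen=True)
class HelicalParameterSet:
    label: str
    steps: dict[str, StepParameters] = field(repr=False)
    pairs: dict[str, PairParameters] = field(repr=False)

    def __post_init__(self):
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.steps)
        if missing:
            raise ValueError(f"missing base steps: {sorted(missing)}")
        if set(self.pairs) != {"A", "C", "G", "T"}:
            raise ValueError("pair parameters must cover A, C, G, T")
        for name, st in self.steps.items():
            if st.rise <= 0:
                raise ValueError(f"step {name}: Rise must be positive")

    def step(self, dinucleotide: str) -> StepParameters:
        """Parameters of the step whose strand-1 reading is ``dinucleotide``."""
        try:
            return self.steps[dinucleotide.upper()]
        except KeyError:
            raise KeyError(f"unknown base step {dinucleotide!r}") from None

    def pair(self, base: str) -> PairParameters:
        """Intra-pair parameters of the pair whose strand-1 base is ``base``."""
        try:
            return self.pairs[base.upper()]
        except KeyError:
            raise KeyError(f"unknown base pair {base!r}") from None

    def symmetrized(self) -> "HelicalParameterSet":
        """Return a copy enforcing exact complementary-step symmetry.

        Step XY and its reverse complement are averaged so that Slide, Rise,
        Roll, Twist agree and Shift, Tilt are exactly opposite.  Useful for
        property tests of strand-exchange symmetry of the rebuild pipeline;
        the printed tables do not satisfy the symmetry exactly for every step.
        """
        comp = str.maketrans("ACGT", "TGCA")
        steps = {}
        for name, st in self.steps.items():
            rc = (name[1] + name[0]).translate(comp)
            other = self.steps[rc]
            steps[name] = StepParameters(
                shift=(st.shift - other.shift) / 2,
                slide=(st.slide + other.slide) / 2,
                rise=(st.rise + other.rise) / 2,
                tilt=(st.tilt - other.tilt) / 2,
                roll=(st.roll + other.roll) / 2,
                twist=(st.twist + other.twist) / 2,
            )
        return HelicalParameterSet(self.label + "-sym", steps, dict(self.pairs))


def load_parameter_set(label: str = "i") -> HelicalParameterSet:
    """Load a packaged helical parameter set by label ("i", "ii", "iii")."""
    label = str(label).lower().strip("()")
    if label not in KNOWN_LABELS:
        raise KeyError(
            f"unknown parameter set {label!r}; known labels: {KNOWN_LABELS}, "
            f"bundled: {tuple(_BUNDLED)}"
        )
    if label not in _BUNDLED:
        raise KeyError(
            f"parameter set ({label}) is recognized but not bundled with this "
            f"package (its source table is not distributed); bundled sets: "
            f"{tuple(_BUNDLED)}"
        )
    ref = importlib.resources.files("dnaenm.data") / _BUNDLED[label]
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", comment="#")
    steps = {}
    pairs = {}
    for row in table.itertuples(index=False):
        values = [float(getattr(row, f"p{k}")) for k in range(1, 7)]
        if row.kind == "step":
            steps[row.name] = StepParameters(*values)
        elif row.kind == "pair":
            pairs[row.name.split("-")[0]] = PairParameters(*values)
        else:
            raise ValueError(f"unknown row kind {row.kind!r}")
    return HelicalParameterSet(label, steps, pairs)
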