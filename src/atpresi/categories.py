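"""Discrete reclassification of per-residue attributes.

Raw per-residue values (backbone dihedral angles, amino-acid identity,
relative solvent accessibility, secondary structure, hydropathy, polarity)
are mapped to small category alphabets before any feature extraction.  Each
map is total on its domain, and every category alphabet carries one extra
"vacancy" (GAP) category for window positions that fall outside the chain.

The dihedral-angle class boundaries are justified empirically: binding and
non-binding residues occupy 15-degree angle bins with different
probabilities, and the three-class schemes for phi and psi follow the sign
structure of that per-bin probability difference.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AA_ALPHABET",
    "GAP",
    "UNKNOWN",
    "ENERGY_GROUP",
    "HYDRO_CLASS",
    "POLARITY_CLASS",
    "SS_CLASS",
    "classify_phi",
    "classify_psi",
    "energy_group",
    "hydro_class",
    "polarity_class",
    "ss_class",
    "rsa_interval",
    "ProbabilityDifference",
    "probability_difference",
    "CategoryMaps",
]

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for window positions outside the chain ("pseudo-amino acid").
GAP = "-"

#: Nonstandard/unknown residue symbol; mapped to the vacancy category.
UNKNOWN = "X"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# Four energy-based residue groups, ordered by how strongly the group is
# over-represented among binding residues (group 1 most enriched, group 4
# most depleted).
ENERGY_GROUP = {
    **{aa: 1 for aa in "GISTV"},
    **{aa: 2 for aa in "CHM"},
    **{aa: 3 for aa in "FKNRWY"},
    **{aa: 4 for aa in "ADELPQ"},
}

# Six hydropathy classes, from strongly hydrophobic to charged.
HYDRO_CLASS = {
    **{aa: 1 for aa in "AGV"},
    **{aa: 2 for aa in "ILFP"},
    **{aa: 3 for aa in "YMTS"},
    **{aa: 4 for aa in "HNQW"},
    **{aa: 5 for aa in "RK"},
    **{aa: 6 for aa in "DE"},
    "C": 3,
}

# Four polarity classes: nonpolar, polar-uncharged, acidic, basic.
POLARITY_CLASS = {
    **{aa: 1 for aa in "AVLIPFWMG"},
    **{aa: 2 for aa in "STCYNQ"},
    **{aa: 3 for aa in "DE"},
    **{aa: 4 for aa in "KRH"},
}

#: Three-state secondary structure: alpha-helix, beta-sheet, coil.
SS_CLASS = {"H": 1, "E": 2, "C": 3}

# Half-open interval schemes for the three-class dihedral reclassification.
# Each scheme is left-closed/right-open except the final interval, so every
# angle in [-180, 180] maps to exactly one class.
PHI_BOUNDS = (-90.0, -60.0)
PSI_BOUNDS = (-60.0, 0.0)

#: RSA interval upper bounds; values above the last printed bound (0.85)
#: clamp into interval 4, and exactly 0 maps to interval 1.
RSA_BOUNDS = (0.2, 0.45, 0.6)


def _check_angle(angle: float) -> None:
    if not -180.0 <= angle <= 180.0:
        raise ValueError(f"angle {angle!r} outside [-180, 180] degrees")


def classify_phi(angle: float) -> int:
    """Map a phi angle (degrees) to class 1 (I), 2 (II) or 3 (III).

    Classes: [-180, -90) -> 1, [-90, -60) -> 2, [-60, 180] -> 3.
    """
    _check_angle(angle)
    if angle < PHI_BOUNDS[0]:
        return 1
    if angle < PHI_BOUNDS[1]:
        return 2
    return 3


def classify_psi(angle: float) -> int:
    """Map a psi angle (degrees) to class 1 (I), 2 (II) or 3 (III).

    Classes: [-180, -60) -> 1, [-60, 0) -> 2, [0, 180] -> 3.
    """
    _check_angle(angle)
    if angle < PSI_BOUNDS[0]:
        return 1
    if angle < PSI_BOUNDS[1]:
        return 2
    return 3


def _lookup(table: dict[str, int], aa: str, allow_unknown: bool) -> int:
    """Look up a residue letter; 0 denotes the vacancy category."""
    if aa == GAP or (allow_unknown and aa == UNKNOWN):
        return 0
    try:
        return table[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid letter {aa!r}") from None


def energy_group(aa: str, allow_unknown: bool = False) -> int:
    """Energy group (1-4) of an amino acid; GAP/'X' -> 0 (vacancy)."""
    return _lookup(ENERGY_GROUP, aa, allow_unknown)


def hydro_class(aa: str, allow_unknown: bool = False) -> int:
    """Hydropathy class (1-6) of an amino acid; GAP/'X' -> 0 (vacancy)."""
    return _lookup(HYDRO_CLASS, aa, allow_unknown)


def polarity_class(aa: str, allow_unknown: bool = False) -> int:
    """Polarity class (1-4) of an amino acid; GAP/'X' -> 0 (vacancy)."""
    return _lookup(POLARITY_CLASS, aa, allow_unknown)


def ss_class(ss: str) -> int:
    """Secondary-structure class: H -> 1, E -> 2, C -> 3; GAP -> 0."""
    if ss == GAP:
        return 0
    try:
        return SS_CLASS[ss]
    except KeyError:
        raise ValueError(f"unknown secondary-structure symbol {ss!r}") from None


def rsa_interval(rsa: float) -> int:
    """Map relative solvent accessibility in [0, 1] to interval 1-4.

    Intervals are [0, 0.2], (0.2, 0.45], (0.45, 0.6], (0.6, 1]; the nominal
    scheme covers (0, 0.85], with rsa == 0 absorbed into interval 1 and
    rsa > 0.85 into interval 4 as limiting cases.
    """
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"rsa {rsa!r} outside [0, 1]")
    for k, bound in enumerate(RSA_BOUNDS, start=1):
        if rsa <= bound:
            return k
    return 4


@dataclass
class ProbabilityDifference:
    """Per-bin probability difference between positive and negative angles.

    ``delta[i] = counts_pos[i]/sum(counts_pos) - counts_neg[i]/sum(counts_neg)``
    over 24 bins of 15 degrees tiling [-180, 180).
    """

    delta: np.ndarray
    counts_pos: np.ndarray
    counts_neg: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.delta)


def probability_difference(
    angles_pos, angles_neg, bin_width: float = 15.0
) -> ProbabilityDifference:
    """Per-bin probability difference of an angle between the two classes.

    Angles of exactly +180 degrees fold to -180 before binning so that the
    bins tile the circle.  Raises if either class is empty.
    """
    angles_pos = np.asarray(angles_pos, dtype=float)
    angles_neg = np.asarray(angles_neg, dtype=float)
    if angles_pos.size == 0 or angles_neg.size == 0:
        raise ValueError("both angle classes must be non-empty")
    for arr in (angles_pos, angles_neg):
        if np.any(arr < -180.0) or np.any(arr > 180.0):
            raise ValueError("angles outside [-180, 180] degrees")
    n_bins = int(round(360.0 / bin_width))
    if n_bins * bin_width != 360.0:
        raise ValueError("bin width must divide 360 degrees")
    edges = -180.0 + bin_width * np.arange(n_bins + 1)

    def _hist(a: np.ndarray) -> np.ndarray:
        folded = np.where(a == 180.0, -180.0, a)
        counts, _ = np.histogram(folded, bins=edges)
        return counts.astype(np.int64)

    counts_pos = _hist(angles_pos)
    counts_neg = _hist(angles_neg)
    delta = counts_pos / counts_pos.sum() - counts_neg / counts_neg.sum()
    return ProbabilityDifference(delta, counts_pos, counts_neg, edges)


@dataclass
class CategoryMaps:
    """Bundle of the editable category tables used by the encoders.

    The hydropathy and polarity partitions are package defaults (they are
    conventional groupings, configurable because reasonable alternatives
    exist); the energy groups, dihedral schemes and RSA intervals are fixed
    by the method.
    """

    energy_group: dict = field(default_factory=lambda: dict(ENERGY_GROUP))
    hydro_class: dict = field(default_factory=lambda: dict(HYDRO_CLASS))
    polarity_class: dict = field(default_factory=lambda: dict(POLARITY_CLASS))
    ss_class: dict = field(default_factory=lambda: dict(SS_CLASS))

    @classmethod
    def from_toml(cls, path) -> "CategoryMaps":
        """Load editable tables from a ``[categories]`` TOML section.

        Each key (``energy_group``, ``hydro_class``, ``polarity_class``,
        ``ss_class``) maps class numbers (as strings) to symbol strings,
        e.g. ``hydro_class = {"1" = "AGV", "2" = "ILFP", ...}``.  Missing
        keys keep the package defaults.
        """
        import tomllib

        with open(path, "rb") as fh:
            section = tomllib.load(fh).get("categories", {})
        maps = cls()
        for name in ("energy_group", "hydro_class", "polarity_class", "ss_class"):
            if name in section:
                table = {
                    symbol: int(klass)
                    for klass, symbols in section[name].items()
                    for symbol in symbols
                }
                setattr(maps, name, table)
        maps.validate()
        return maps

    def n_classes(self, name: str) -> int:
        return max(getattr(self, name).values())

    def checksum(self) -> str:
        """Stable hex digest of all tables, for run provenance logs."""
        blob = json.dumps(
            {
                "energy": self.energy_group,
                "hydro": self.hydro_class,
                "polarity": self.polarity_class,
                "ss": self.ss_class,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("energy_group", "hydro_class", "polarity_class"):
            table = getattr(self, name)
            missing = set(AA_ALPHABET) - set(table)
            if missing:
                raise ValueError(f"{name} does not cover residues {sorted(missing)}")


# Vectorised helpers used by the featurizer (0 = vacancy everywhere).

def classify_phi_array(angles: np.ndarray) -> np.ndarray:
    """Vectorised phi classes; NaN (GAP positions) -> 0."""
    out = np.full(angles.shape, 3, dtype=np.int8)
    out[angles < PHI_BOUNDS[1]] = 2
    out[angles < PHI_BOUNDS[0]] = 1
    out[np.isnan(angles)] = 0
    return out


def classify_psi_array(angles: np.ndarray) -> np.ndarray:
    """Vectorised psi classes; NaN (GAP positions) -> 0."""
    out = np.full(angles.shape, 3, dtype=np.int8)
    out[angles < PSI_BOUNDS[1]] = 2
    out[angles < PSI_BOUNDS[0]] = 1
    out[np.isnan(angles)] = 0
    return out


def rsa_interval_array(rsa: np.ndarray) -> np.ndarray:
    """Vectorised RSA intervals; NaN (GAP positions) -> 0."""
    out = np.full(rsa.shape, 4, dtype=np.int8)
    out[rsa <= RSA_BOUNDS[2]] = 3
    out[rsa <= RSA_BOUNDS[1]] = 2
    out[rsa <= RSA_BOUNDS[0]] = 1
    out[np.isnan(rsa)] = 0
    return out
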