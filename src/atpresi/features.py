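"""Fragment featurization: propensity factors, composition, position weight
matrices and hydropathy entropy.

Every fragment is encoded over six categorical properties -- amino acid
(q=21), secondary structure (q=4), RSA interval (q=5), energy group (q=5),
phi class (q=4) and psi class (q=4) -- where the extra category in each
alphabet is the window vacancy (GAP).  From these the featurizer assembles,
per fragment:

* composition: the 21+4+5+4+4+5 = 43 per-property frequency vectors over
  the window (each sums to 1);
* site conservation: per-position log-odds ``m = ln(p/p0)`` against two
  position weight matrices fitted on the positive and negative training
  fragments respectively -- 2L values per property, 6 x 2L in total;
* hydropathy entropy: the Shannon entropy (base 2) of the fragment's
  hydropathy-class distribution, q = 7 categories including the vacancy;
* propensity factors: for each window position the binding and non-binding
  propensity of the residue occupying it (2L values), where a propensity is
  the residue's class-conditional frequency over its background frequency;
* optionally, per-position one-hot hydropathy (7) and polarity (5) classes.

All tables are fitted on training fragments only; transforming a fragment
never touches its label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import categories as cat
from .categories import AA_ALPHABET, CategoryMaps, GAP, UNKNOWN
from .chains import Fragment

__all__ = [
    "PropensityTable",
    "ScoringMatrixPair",
    "FragmentFeaturizer",
    "fit_propensity",
    "propensity_features",
    "composition_block",
    "fit_scoring_matrices",
    "pwm_features",
    "hydro_entropy",
    "assemble_features",
    "FEATURE_SETS",
    "PROPERTY_Q",
]

#: Per-property alphabet sizes, vacancy included.
PROPERTY_Q = {"aa": 21, "ss": 4, "rsa": 5, "energy": 5, "phi": 4, "psi": 4}

#: Valid feature-set names (B = basic; F/PP/E add propensity factors,
#: dihedral-angle blocks and energy blocks respectively).
FEATURE_SETS = ("B", "B+E", "B+PP", "B+F", "B+F+E", "B+F+PP", "B+F+PP+E")

_N_HYDRO = 7  # six hydropathy classes + vacancy
_N_POLAR = 5  # four polarity classes + vacancy


def _aa_lut(maps: CategoryMaps) -> dict[str, np.ndarray]:
    """Byte-indexed lookup tables from residue letter to category index.

    Category indices are 0-based with the vacancy category LAST in every
    alphabet; GAP and the unknown symbol both map to the vacancy.
    """
    luts = {}
    specs = {
        "aa": ({aa: i for i, aa in enumerate(AA_ALPHABET)}, 21),
        "energy": ({k: v - 1 for k, v in maps.energy_group.items()}, 5),
        "hydro": ({k: v - 1 for k, v in maps.hydro_class.items()}, _N_HYDRO),
        "polarity": ({k: v - 1 for k, v in maps.polarity_class.items()}, _N_POLAR),
    }
    for name, (table, q) in specs.items():
        lut = np.full(256, -1, dtype=np.int16)
        for aa, idx in table.items():
            lut[ord(aa)] = idx
        lut[ord(GAP)] = q - 1
        lut[ord(UNKNOWN)] = q - 1
        luts[name] = lut
    ss_lut = np.full(256, -1, dtype=np.int16)
    for sym, idx in maps.ss_class.items():
        ss_lut[ord(sym)] = idx - 1
    ss_lut[ord(GAP)] = 3
    luts["ss"] = ss_lut
    return luts


def encode_fragments(fragments: list[Fragment], maps: CategoryMaps | None = None):
    """Encode fragments as per-property (n, L) integer category matrices.

    Returns ``(codes, labels)`` where ``codes`` maps property name ->
    matrix of 0-based category indices (vacancy last).
    """
    if not fragments:
        raise ValueError("no fragments to encode")
    maps = maps or CategoryMaps()
    L = fragments[0].L
    if any(f.L != L for f in fragments):
        raise ValueError("fragments have inconsistent window lengths")
    luts = _aa_lut(maps)

    seq_bytes = np.frombuffer(
        "".join(f.residues for f in fragments).encode("ascii"), dtype=np.uint8
    ).reshape(len(fragments), L)
    codes = {name: luts[name][seq_bytes] for name in ("aa", "energy", "hydro", "polarity")}
    for name, arr in codes.items():
        if (arr < 0).any():
            raise ValueError(f"unmappable residue letter for property {name}")

    if fragments[0].ss is not None:
        ss_bytes = np.frombuffer(
            "".join("".join(f.ss) for f in fragments).encode("ascii"), dtype=np.uint8
        ).reshape(len(fragments), L)
        codes["ss"] = luts["ss"][ss_bytes]
        if (codes["ss"] < 0).any():
            raise ValueError("unmappable secondary-structure symbol")
        rsa = np.stack([f.rsa for f in fragments])
        phi = np.stack([f.phi for f in fragments])
        psi = np.stack([f.psi for f in fragments])
        # vacancy (NaN) -> 0 in the 1-based helpers -> remap to q-1 last
        codes["rsa"] = _shift_vacancy(cat.rsa_interval_array(rsa), 5)
        codes["phi"] = _shift_vacancy(cat.classify_phi_array(phi), 4)
        codes["psi"] = _shift_vacancy(cat.classify_psi_array(psi), 4)

    labels = np.array([f.label for f in fragments], dtype=np.int8)
    return codes, labels


def _shift_vacancy(arr_1based: np.ndarray, q: int) -> np.ndarray:
    """1-based classes with 0 = vacancy -> 0-based with vacancy last."""
    out = arr_1based.astype(np.int16) - 1
    out[out < 0] = q - 1
    return out


@dataclass
class PropensityTable:
    """Binding/non-binding propensity factors of the 20 amino acids.

    ``F[i, 0]`` (binding) and ``F[i, 1]`` (non-binding) are the ratio of
    amino acid *i*'s frequency within the class to its background frequency
    over all training centre residues; 1 means no preference.  The
    ``verbatim`` form divides the within-class share ``n_ij / N_j`` by the
    class share ``N_j / N_t`` instead (kept for comparison; it loses the
    per-residue background normalisation).
    """

    F: np.ndarray  # (20, 2)
    counts: np.ndarray  # (20, 2) raw n_ij
    class_totals: np.ndarray  # (2,) N_j
    form: str = "standard"

    def pair(self, aa_index: int) -> tuple[float, float]:
        if aa_index >= 20:  # vacancy / unknown
            return 1.0, 1.0
        return float(self.F[aa_index, 0]), float(self.F[aa_index, 1])


def fit_propensity(
    fragments: list[Fragment], form: str = "standard"
) -> PropensityTable:
    """Fit propensity factors from the centre residues of training fragments."""
    codes, labels = encode_fragments(fragments)
    return _fit_propensity_codes(codes["aa"], labels, fragments[0].L, form)


def _fit_propensity_codes(
    aa_codes: np.ndarray, labels: np.ndarray, L: int, form: str
) -> PropensityTable:
    if form not in ("standard", "verbatim"):
        raise ValueError(f"unknown propensity form {form!r}")
    center = aa_codes[:, (L - 1) // 2]
    keep = center < 20  # centre residues are never GAP; guard unknown 'X'
    center, labels = center[keep], labels[keep]
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes must be present to fit propensity factors")
    counts = np.zeros((20, 2), dtype=np.int64)
    np.add.at(counts[:, 0], center[labels == 1], 1)
    np.add.at(counts[:, 1], center[labels == 0], 1)
    class_totals = counts.sum(axis=0)  # N_j
    n_total = class_totals.sum()  # N_t
    with np.errstate(invalid="ignore", divide="ignore"):
        if form == "standard":
            background = counts.sum(axis=1, keepdims=True) / n_total  # n_i / N_t
            F = (counts / class_totals) / background
        else:
            F = (counts / class_totals) / (class_totals / n_total)
    F = np.where(np.isfinite(F), F, 1.0)  # unseen residue: no preference
    return PropensityTable(F=F, counts=counts, class_totals=class_totals, form=form)


def propensity_features(fragment: Fragment, table: PropensityTable) -> np.ndarray:
    """2L vector: (binding, non-binding) propensity of each window residue."""
    codes, _ = encode_fragments([fragment])
    return _propensity_block(codes["aa"], table)[0]


def _propensity_block(aa_codes: np.ndarray, table: PropensityTable) -> np.ndarray:
    F_ext = np.vstack([table.F, [1.0, 1.0]])  # vacancy row
    return F_ext[aa_codes].reshape(aa_codes.shape[0], -1)


def composition_block(fragment: Fragment, property: str) -> np.ndarray:
    """Frequency vector of a property's categories over the window (sums to 1)."""
    q = PROPERTY_Q[property]
    codes, _ = encode_fragments([fragment])
    return _composition(codes[property], q)[0]


def _composition(codes: np.ndarray, q: int) -> np.ndarray:
    n, L = codes.shape
    out = np.zeros((n, q))
    np.add.at(out, (np.repeat(np.arange(n), L), codes.ravel()), 1.0)
    return out / L


@dataclass
class ScoringMatrixPair:
    """Positive/negative position weight matrices for one property.

    ``m_pos[i, j] = ln(p_ij / p0_j)`` with ``p_ij`` the square-root
    pseudocounted probability of category *j* at window position *i* among
    positive training fragments (``m_neg`` likewise from negatives) and
    ``p0_j`` the pooled background probability with the same smoothing.
    """

    property: str
    m_pos: np.ndarray  # (L, q)
    m_neg: np.ndarray
    p0: np.ndarray  # (q,)

    @property
    def L(self) -> int:
        return self.m_pos.shape[0]

    @property
    def q(self) -> int:
        return self.m_pos.shape[1]


def _pseudo_probs(counts: np.ndarray, n: int, q: int) -> np.ndarray:
    """Square-root pseudocount estimate (n_j + sqrt(N)/q) / (N + sqrt(N))."""
    return (counts + np.sqrt(n) / q) / (n + np.sqrt(n))


def fit_scoring_matrices(
    fragments: list[Fragment], property: str
) -> ScoringMatrixPair:
    """Fit the positive/negative PWM pair for one property on training data."""
    codes, labels = encode_fragments(fragments)
    return _fit_pwm_codes(codes[property], labels, property)


def _fit_pwm_codes(
    codes: np.ndarray, labels: np.ndarray, property: str
) -> ScoringMatrixPair:
    q = PROPERTY_Q[property]
    L = codes.shape[1]
    pos, neg = codes[labels == 1], codes[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to fit scoring matrices")

    def _position_counts(block: np.ndarray) -> np.ndarray:
        counts = np.zeros((L, q))
        np.add.at(counts, (np.tile(np.arange(L), len(block)), block.ravel("C")), 1.0)
        return counts

    bg_counts = np.bincount(codes.ravel(), minlength=q).astype(float)
    p0 = _pseudo_probs(bg_counts, codes.size, q)
    m_pos = np.log(_pseudo_probs(_position_counts(pos), len(pos), q) / p0)
    m_neg = np.log(_pseudo_probs(_position_counts(neg), len(neg), q) / p0)
    return ScoringMatrixPair(property=property, m_pos=m_pos, m_neg=m_neg, p0=p0)


def pwm_features(fragment: Fragment, pairs: dict[str, ScoringMatrixPair]) -> np.ndarray:
    """6 x 2L vector of per-position (positive, negative) log-odds scores."""
    codes, _ = encode_fragments([fragment])
    blocks = [
        _pwm_block(codes[name], pairs[name])
        for name in ("aa", "ss", "rsa", "energy", "phi", "psi")
    ]
    return np.concatenate(blocks, axis=1)[0]


def _pwm_block(codes: np.ndarray, pair: ScoringMatrixPair) -> np.ndarray:
    n, L = codes.shape
    pos_scores = pair.m_pos[np.arange(L), codes]
    neg_scores = pair.m_neg[np.arange(L), codes]
    out = np.empty((n, 2 * L))
    out[:, 0::2] = pos_scores
    out[:, 1::2] = neg_scores
    return out


def hydro_entropy(fragment: Fragment) -> float:
    """Shannon entropy (bits) of the window's hydropathy-class distribution."""
    codes, _ = encode_fragments([fragment])
    return float(_entropy_block(codes["hydro"], _N_HYDRO)[0, 0])


def _entropy_block(codes: np.ndarray, q: int) -> np.ndarray:
    p = _composition(codes, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1, keepdims=True)


def _onehot_block(codes: np.ndarray, q: int) -> np.ndarray:
    n, L = codes.shape
    out = np.zeros((n, L * q))
    out[np.arange(n)[:, None], np.arange(L) * q + codes] = 1.0
    return out


def _parse_feature_set(feature_set: str) -> set[str]:
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; one of {FEATURE_SETS}")
    return set(feature_set.split("+"))


class FragmentFeaturizer(TransformerMixin, BaseEstimator):
    """Supervised transformer from fragments to flat feature vectors.

    Parameters
    ----------
    feature_set : str
        One of ``B, B+E, B+PP, B+F, B+F+E, B+F+PP, B+F+PP+E``.  B carries
        the amino-acid / secondary-structure / RSA composition and PWM
        blocks, the hydropathy entropy and (if ``b_onehot``) per-position
        hydropathy and polarity one-hots; PP adds the phi/psi blocks, E the
        energy blocks, F the propensity-factor block.
    b_onehot : bool
        Include the per-position hydropathy/polarity one-hot blocks in B.
    propensity_form : str
        ``"standard"`` (class frequency over background frequency) or
        ``"verbatim"`` (within-class share over class share).
    maps : CategoryMaps or None
        Category tables; defaults are the package tables.

    Attributes
    ----------
    layout_ : list of (block name, width)
    propensity_ : PropensityTable (when F is in the feature set)
    pwm_pairs_ : dict of property -> ScoringMatrixPair
    n_features_out_ : int
    """

    def __init__(
        self,
        feature_set: str = "B+F+PP+E",
        b_onehot: bool = True,
        propensity_form: str = "standard",
        maps: CategoryMaps | None = None,
    ):
        self.feature_set = feature_set
        self.b_onehot = b_onehot
        self.propensity_form = propensity_form
        self.maps = maps

    def _blocks(self, L: int) -> list[tuple[str, int]]:
        parts = _parse_feature_set(self.feature_set)
        comp_props = ["aa", "ss", "rsa"]
        if "PP" in parts:
            comp_props += ["phi", "psi"]
        if "E" in parts:
            comp_props += ["energy"]
        layout = [(f"comp_{p}", PROPERTY_Q[p]) for p in comp_props]
        layout += [(f"pwm_{p}", 2 * L) for p in comp_props]
        layout.append(("entropy_hydro", 1))
        if self.b_onehot:
            layout.append(("onehot_hydro", _N_HYDRO * L))
            layout.append(("onehot_polarity", _N_POLAR * L))
        if "F" in parts:
            layout.append(("propensity", 2 * L))
        return layout

    def fit(self, fragments: list[Fragment], y=None):
        """Fit propensity and PWM tables on labelled training fragments."""
        maps = self.maps or CategoryMaps()
        codes, labels = encode_fragments(fragments, maps)
        if y is not None:
            labels = np.asarray(y, dtype=np.int8)
        L = fragments[0].L
        parts = _parse_feature_set(self.feature_set)
        self.L_ = L
        self.layout_ = self._blocks(L)
        self.n_features_out_ = sum(w for _, w in self.layout_)
        props = [name[4:] for name, _ in self.layout_ if name.startswith("pwm_")]
        if any(p in ("ss", "rsa", "phi", "psi") for p in props) and "ss" not in codes:
            raise ValueError("fragments lack per-residue attributes")
        self.pwm_pairs_ = {p: _fit_pwm_codes(codes[p], labels, p) for p in props}
        if "F" in parts:
            self.propensity_ = _fit_propensity_codes(
                codes["aa"], labels, L, self.propensity_form
            )
        return self

    def transform(self, fragments: list[Fragment]) -> np.ndarray:
        """Feature matrix (n_fragments, n_features_out_); label-free."""
        if not hasattr(self, "layout_"):
            raise ValueError("featurizer is not fitted")
        maps = self.maps or CategoryMaps()
        codes, _ = encode_fragments(fragments, maps)
        if fragments[0].L != self.L_:
            raise ValueError("window length differs from the fitted length")
        blocks = []
        for name, _ in self.layout_:
            kind, _, prop = name.partition("_")
            if kind == "comp":
                blocks.append(_composition(codes[prop], PROPERTY_Q[prop]))
            elif kind == "pwm":
                blocks.append(_pwm_block(codes[prop], self.pwm_pairs_[prop]))
            elif kind == "entropy":
                blocks.append(_entropy_block(codes["hydro"], _N_HYDRO))
            elif kind == "onehot":
                q = _N_HYDRO if prop == "hydro" else _N_POLAR
                blocks.append(_onehot_block(codes[prop], q))
            elif kind == "propensity":
                blocks.append(_propensity_block(codes["aa"], self.propensity_))
        return np.concatenate(blocks, axis=1)

    def feature_names(self) -> list[str]:
        names = []
        for block, width in self.layout_:
            names.extend(f"{block}_{k}" for k in range(width))
        return names


def assemble_features(
    fragment: Fragment, feature_set: str, featurizer: FragmentFeaturizer
) -> np.ndarray:
    """Feature vector of one fragment under a fitted featurizer."""
    if featurizer.feature_set != feature_set:
        raise ValueError(
            f"featurizer was fitted for {featurizer.feature_set!r}, not {feature_set!r}"
        )
    return featurizer.transform([fragment])[0]
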