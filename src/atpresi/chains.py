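"""Chain records, attribute tables, sliding-window fragments and CV splits.

A :class:`ProteinChain` couples a sequence with per-residue binary binding
labels and the per-residue predicted attributes (secondary-structure class,
relative solvent accessibility, phi/psi angles) the encoders consume.
Chains are segmented into odd-length windows (:class:`Fragment`) centred on
each residue, padded with GAP pseudo-residues at the chain ends; a fragment
is positive iff its centre residue is a binding residue.

Residue indices are 0-based in memory and 1-based in every file format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .categories import AA_ALPHABET, GAP, UNKNOWN

__all__ = [
    "ProteinChain",
    "Fragment",
    "DatasetSplit",
    "read_chain_file",
    "write_chain_file",
    "merge_attributes",
    "make_fragments",
    "assign_folds",
    "save_dataset",
    "load_dataset",
]

_SS_SYMBOLS = frozenset("HEC")


@dataclass
class ProteinChain:
    """A protein chain with per-residue binding labels and attributes.

    ``labels[i] == 1`` marks residue ``i`` as ATP-binding.  Attribute arrays
    (``ss``, ``rsa``, ``phi``, ``psi``) are ``None`` until merged from an
    attribute table.
    """

    chain_id: str
    sequence: str
    labels: np.ndarray
    ss: np.ndarray | None = None
    rsa: np.ndarray | None = None
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_attributes(self) -> bool:
        return self.ss is not None

    def validate(self, allow_unknown: bool = False) -> None:
        alphabet = set(AA_ALPHABET) | ({UNKNOWN} if allow_unknown else set())
        for pos, aa in enumerate(self.sequence):
            if aa not in alphabet:
                raise ValueError(
                    f"chain {self.chain_id}: non-alphabet residue {aa!r} "
                    f"at position {pos + 1}"
                )
        if len(self.labels) != len(self.sequence):
            raise ValueError(
                f"chain {self.chain_id}: label length {len(self.labels)} != "
                f"sequence length {len(self.sequence)}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError(f"chain {self.chain_id}: labels must be 0/1")
        if self.has_attributes:
            for name in ("ss", "rsa", "phi", "psi"):
                arr = getattr(self, name)
                if arr is None or len(arr) != len(self.sequence):
                    raise ValueError(
                        f"chain {self.chain_id}: attribute {name} misaligned"
                    )
            if np.any(self.rsa < 0) or np.any(self.rsa > 1):
                raise ValueError(f"chain {self.chain_id}: rsa outside [0, 1]")
            for name in ("phi", "psi"):
                arr = getattr(self, name)
                if np.any(arr < -180) or np.any(arr > 180):
                    raise ValueError(
                        f"chain {self.chain_id}: angle out of range in {name}"
                    )
            bad = set(np.asarray(self.ss)) - _SS_SYMBOLS
            if bad:
                raise ValueError(
                    f"chain {self.chain_id}: unknown ss symbols {sorted(bad)}"
                )


@dataclass
class Fragment:
    """An L-residue window centred on one residue of a chain.

    GAP symbols (and NaN attribute entries) occupy window positions whose
    absolute chain coordinate falls outside ``[0, len(chain))``.
    """

    chain_id: str
    center_index: int
    residues: str
    label: int
    ss: np.ndarray | None = None
    rsa: np.ndarray | None = None
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass
class DatasetSplit:
    """Chain-level train/test partition with per-chain CV fold ids (1-based)."""

    train_chains: list[ProteinChain]
    test_chains: list[ProteinChain] = field(default_factory=list)
    fold_assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        train_ids = {c.chain_id for c in self.train_chains}
        test_ids = {c.chain_id for c in self.test_chains}
        overlap = train_ids & test_ids
        if overlap:
            raise ValueError(f"train/test chain ids overlap: {sorted(overlap)}")

    def folds(self) -> list[int]:
        return sorted(set(self.fold_assignments.values()))

    def fold_chains(self, fold: int) -> tuple[list[ProteinChain], list[ProteinChain]]:
        """(training chains, held-out chains) for one CV fold."""
        held = [c for c in self.train_chains if self.fold_assignments[c.chain_id] == fold]
        rest = [c for c in self.train_chains if self.fold_assignments[c.chain_id] != fold]
        return rest, held


def _parse_label_string(chain_id: str, seq: str, lab: str) -> np.ndarray:
    lab = lab.strip()
    if len(lab) != len(seq):
        raise ValueError(
            f"chain {chain_id}: label length mismatch "
            f"({len(lab)} labels for {len(seq)} residues)"
        )
    if set(lab) - {"0", "1"}:
        raise ValueError(f"chain {chain_id}: labels must be a 0/1 string")
    return np.frombuffer(lab.encode(), dtype=np.uint8) - ord("0")


def read_chain_file(
    path,
    dialect: str = "fasta_plus_labels",
    labels_path=None,
    allow_unknown: bool = False,
) -> list[ProteinChain]:
    """Read labelled chains.

    ``fasta_plus_labels``: FASTA at *path*, plus a parallel label file
    (``labels_path``, default *path* with suffix ``.lab``) holding records
    ``>id`` followed by a 0/1 string per chain.

    ``sdcnn_github``: a single interleaved text file of repeating
    ``>id`` / sequence / 0-1 label-string triples (the layout the deposited
    ATP datasets use); tolerant of blank lines and of labels written with
    separators.
    """
    path = Path(path)
    if dialect == "fasta_plus_labels":
        records = list(SeqIO.parse(str(path), "fasta"))
        labels_path = Path(labels_path) if labels_path else path.with_suffix(".lab")
        label_map = _read_label_records(labels_path)
        chains = []
        for rec in records:
            if rec.id not in label_map:
                raise ValueError(f"chain {rec.id}: no label record")
            seq = str(rec.seq).upper()
            chain = ProteinChain(rec.id, seq, _parse_label_string(rec.id, seq, label_map[rec.id]))
            chain.validate(allow_unknown=allow_unknown)
            chains.append(chain)
        return chains
    if dialect == "sdcnn_github":
        return _read_interleaved(path, allow_unknown)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_label_records(path: Path) -> dict[str, str]:
    label_map: dict[str, str] = {}
    current = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            label_map[current] = ""
        elif current is not None:
            label_map[current] += line
        else:
            raise ValueError(f"label file {path}: data before first '>' header")
    return label_map


def _read_interleaved(path: Path, allow_unknown: bool) -> list[ProteinChain]:
    """Best-effort parser for interleaved id/sequence/labels triples."""
    chains = []
    blocks: list[tuple[str, list[str]]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            blocks.append((line[1:].split()[0], []))
        else:
            if not blocks:
                raise ValueError(f"{path}: data before first '>' header")
            blocks[-1][1].append(line)
    for chain_id, lines in blocks:
        seq_parts, lab_parts = [], []
        for line in lines:
            stripped = line.replace(" ", "").replace(",", "").replace("\t", "")
            if set(stripped) <= {"0", "1"}:
                lab_parts.append(stripped)
            else:
                seq_parts.append(stripped.upper())
        seq = "".join(seq_parts)
        lab = "".join(lab_parts)
        if not seq or not lab:
            raise ValueError(f"chain {chain_id}: missing sequence or label lines")
        chain = ProteinChain(chain_id, seq, _parse_label_string(chain_id, seq, lab))
        chain.validate(allow_unknown=allow_unknown)
        chains.append(chain)
    return chains


def write_chain_file(chains: Sequence[ProteinChain], path, labels_path=None) -> None:
    """Write chains in the native fasta_plus_labels dialect (UTF-8, LF)."""
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else path.with_suffix(".lab")
    with open(path, "w", newline="\n") as fa, open(labels_path, "w", newline="\n") as lf:
        for chain in chains:
            fa.write(f">{chain.chain_id}\n{chain.sequence}\n")
            lf.write(f">{chain.chain_id}\n{''.join(map(str, chain.labels))}\n")


def merge_attributes(chains: Sequence[ProteinChain], table) -> list[ProteinChain]:
    """Attach per-residue attributes from a tab-separated table.

    *table* is a path to a TSV with columns ``chain_id, residue_index (1-based),
    ss, rsa, phi, psi``, or an equivalent :class:`pandas.DataFrame`.  Every
    residue of every chain must be covered exactly once; rows for unknown
    chains or out-of-range indices are hard errors.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t")
    required = {"chain_id", "residue_index", "ss", "rsa", "phi", "psi"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"attribute table missing columns {sorted(missing_cols)}")

    by_chain = {cid: grp for cid, grp in table.groupby("chain_id")}
    out = []
    for chain in chains:
        grp = by_chain.pop(chain.chain_id, None)
        if grp is None:
            raise ValueError(f"chain {chain.chain_id}: no attribute rows")
        idx = grp["residue_index"].to_numpy()
        n = len(chain)
        bad = idx[(idx < 1) | (idx > n)]
        if bad.size:
            raise ValueError(
                f"chain {chain.chain_id}: residue_index out of range: "
                f"{sorted(set(bad.tolist()))} (chain length {n})"
            )
        missing = sorted(set(range(1, n + 1)) - set(idx.tolist()))
        if missing or len(idx) != len(set(idx.tolist())):
            raise ValueError(
                f"chain {chain.chain_id}: attribute rows missing or duplicated "
                f"for residues {missing or 'duplicates'}"
            )
        order = np.argsort(idx)
        attributed = replace(
            chain,
            ss=grp["ss"].to_numpy(dtype="U1")[order],
            rsa=grp["rsa"].to_numpy(dtype=float)[order],
            phi=grp["phi"].to_numpy(dtype=float)[order],
            psi=grp["psi"].to_numpy(dtype=float)[order],
        )
        attributed.validate()
        out.append(attributed)
    if by_chain:
        raise ValueError(f"attribute rows for unknown chains: {sorted(by_chain)}")
    return out


def attribute_table(chains: Iterable[ProteinChain]) -> pd.DataFrame:
    """Per-residue attribute table (1-based indices) for a set of chains."""
    rows = []
    for chain in chains:
        if not chain.has_attributes:
            raise ValueError(f"chain {chain.chain_id}: attributes unset")
        for i in range(len(chain)):
            rows.append(
                (chain.chain_id, i + 1, chain.ss[i], chain.rsa[i], chain.phi[i], chain.psi[i])
            )
    return pd.DataFrame(
        rows, columns=["chain_id", "residue_index", "ss", "rsa", "phi", "psi"]
    )


def make_fragments(chain: ProteinChain, L: int = 17) -> list[Fragment]:
    """Segment a chain into L-residue windows, one centred on each residue.

    ``(L-1)/2`` GAP pseudo-residues pad each end, so the fragment count
    equals the residue count and the fragment label is the centre residue's
    label.
    """
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length L must be odd and >= 1, got {L}")
    half = (L - 1) // 2
    n = len(chain)
    padded_seq = GAP * half + chain.sequence + GAP * half

    def _pad(arr, fill):
        if arr is None:
            return None
        full = np.full(n + 2 * half, fill, dtype=arr.dtype if arr.dtype.kind != "U" else "U1")
        full[half : half + n] = arr
        return full

    ss = _pad(chain.ss, GAP)
    rsa = _pad(chain.rsa, np.nan)
    phi = _pad(chain.phi, np.nan)
    psi = _pad(chain.psi, np.nan)

    fragments = []
    for i in range(n):
        sl = slice(i, i + L)
        fragments.append(
            Fragment(
                chain_id=chain.chain_id,
                center_index=i,
                residues=padded_seq[sl],
                label=int(chain.labels[i]),
                ss=None if ss is None else ss[sl],
                rsa=None if rsa is None else rsa[sl],
                phi=None if phi is None else phi[sl],
                psi=None if psi is None else psi[sl],
            )
        )
    return fragments


def fragments_of(chains: Iterable[ProteinChain], L: int = 17) -> list[Fragment]:
    """All fragments of all chains, in chain order."""
    out: list[Fragment] = []
    for chain in chains:
        out.extend(make_fragments(chain, L=L))
    return out


def assign_folds(
    chains: Sequence[ProteinChain], n_folds: int = 5, seed: int = 0
) -> DatasetSplit:
    """Random chain-level fold assignment with sizes differing by at most 1.

    All fragments of a chain share its fold, so near-duplicate windows from
    one chain never straddle a fold boundary.
    """
    if len(chains) < n_folds:
        raise ValueError(f"need at least {n_folds} chains, got {len(chains)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chains))
    assignments = {
        chains[idx].chain_id: (k % n_folds) + 1 for k, idx in enumerate(order)
    }
    return DatasetSplit(train_chains=list(chains), fold_assignments=assignments)


def save_dataset(chains: Sequence[ProteinChain], path) -> None:
    """Serialise attributed chains to a JSON dataset file."""
    payload = {"format": "atpresi-dataset-v1", "chains": []}
    for chain in chains:
        entry = {
            "chain_id": chain.chain_id,
            "sequence": chain.sequence,
            "labels": "".join(map(str, chain.labels)),
        }
        if chain.has_attributes:
            entry.update(
                ss="".join(chain.ss),
                rsa=[round(float(v), 6) for v in chain.rsa],
                phi=[round(float(v), 4) for v in chain.phi],
                psi=[round(float(v), 4) for v in chain.psi],
            )
        payload["chains"].append(entry)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_dataset(path) -> list[ProteinChain]:
    payload = json.loads(Path(path).read_text())
    chains = []
    for entry in payload["chains"]:
        chain = ProteinChain(
            entry["chain_id"],
            entry["sequence"],
            _parse_label_string(entry["chain_id"], entry["sequence"], entry["labels"]),
        )
        if "ss" in entry:
            chain = replace(
                chain,
                ss=np.array(list(entry["ss"]), dtype="U1"),
                rsa=np.array(entry["rsa"], dtype=float),
                phi=np.array(entry["phi"], dtype=float),
                psi=np.array(entry["psi"], dtype=float),
            )
        chain.validate()
        chains.append(chain)
    return chains
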