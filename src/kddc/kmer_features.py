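"""K-mer featurization of CDR3 amino-acid sequences.

Sequences are segmented into overlapping k-mers (step 1). The feature space
for a set of k values is the complete enumeration of amino-acid concatemers:
20^k columns per k over the standard alphabet (400 for k=2, 8000 for k=3,
160,000 for k=4), lexicographically ordered within each k block, k blocks in
ascending order. Count matrices are zero-filled: every possible concatemer
has a column even if it never occurs.

Rows of a count matrix are (sample, cell subset) repertoires by default;
classification of disease state is a per-sample property. A per-cell row
unit is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .repertoire_io import AA_ALPHABET, Cdr3Record


@dataclass(frozen=True)
class FeatureSpace:
    """Complete ordered enumeration of amino-acid concatemers for a k-set."""

    ks: tuple[int, ...]
    alphabet: str
    columns: tuple[str, ...]
    index: Mapping[str, int]

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.columns)


def enumerate_feature_space(ks: Iterable[int], alphabet: str = AA_ALPHABET) -> FeatureSpace:
    """Enumerate all |alphabet|^k concatemers for every k, in deterministic order.

    Columns are lexicographic within each k block (for a sorted alphabet);
    blocks appear in ascending k.
    """
    ks = tuple(sorted({int(k) for k in ks}))
    if not ks:
        raise ValueError("ks must be non-empty")
    if any(k < 1 for k in ks):
        raise ValueError(f"all k values must be >= 1, got {ks}")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet letters must be unique")
    columns = tuple(
        "".join(p) for k in ks for p in product(alphabet, repeat=k)
    )
    index = {kmer: i for i, kmer in enumerate(columns)}
    return FeatureSpace(ks=ks, alphabet=alphabet, columns=columns, index=index)


def segment_kmers(seq: str, k: int, alphabet: str = AA_ALPHABET) -> list[str]:
    """All overlapping windows of length k, left to right.

    Windows containing characters outside ``alphabet`` are omitted, so
    non-standard residues never create out-of-space features.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    alpha = set(alphabet)
    return [
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if set(seq[i : i + k]) <= alpha
    ]


@dataclass
class KmerCountMatrix:
    """Zero-filled concatemer count matrix with aligned class labels.

    ``row_keys`` are (sample_id, subset) pairs (or (cell_barcode, subset)
    under the per-cell row unit); ``labels`` holds one disease-state code
    per row.
    """

    row_keys: list[tuple[str, str]]
    feature_space: FeatureSpace
    counts: sparse.csr_matrix
    labels: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()

    def to_dataframe(self) -> pd.DataFrame:
        """Dense wide table; intended for small matrices only."""
        df = pd.DataFrame(
            self.counts.toarray(),
            columns=list(self.feature_space.columns),
            index=pd.MultiIndex.from_tuples(self.row_keys, names=["sample_id", "subset"]),
        )
        return df

    def row_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [k[0] for k in self.row_keys],
                "subset": [k[1] for k in self.row_keys],
                "state": self.labels,
            }
        )

    def normalized(self) -> "KmerCountMatrix":
        """Per-row relative frequencies (counts divided by the row sum)."""
        sums = np.asarray(self.counts.sum(axis=1)).ravel()
        sums[sums == 0] = 1.0
        scaled = sparse.diags(1.0 / sums) @ self.counts.astype(float)
        return KmerCountMatrix(
            row_keys=list(self.row_keys),
            feature_space=self.feature_space,
            counts=scaled.tocsr(),
            labels=self.labels.copy(),
        )

    def save(self, out_dir: str | Path, name: str = "counts") -> None:
        """Export as MatrixMarket + columns.txt + rows.csv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(out_dir / f"{name}.mtx"), self.counts)
        (out_dir / f"{name}.columns.txt").write_text(
            "\n".join(self.feature_space.columns) + "\n"
        )
        self.row_frame().to_csv(out_dir / f"{name}.rows.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path, name: str = "counts") -> "KmerCountMatrix":
        out_dir = Path(out_dir)
        counts = sparse.csr_matrix(mmread(str(out_dir / f"{name}.mtx")))
        columns = (out_dir / f"{name}.columns.txt").read_text().split()
        ks = tuple(sorted({len(c) for c in columns}))
        alphabet = "".join(sorted({ch for c in columns for ch in c}))
        fs = FeatureSpace(
            ks=ks,
            alphabet=alphabet,
            columns=tuple(columns),
            index={c: i for i, c in enumerate(columns)},
        )
        rows = pd.read_csv(out_dir / f"{name}.rows.csv", dtype={"sample_id": str, "subset": str})
        row_keys = list(zip(rows["sample_id"], rows["subset"]))
        return cls(row_keys=row_keys, feature_space=fs, counts=counts,
                   labels=rows["state"].to_numpy(dtype=int))


def build_count_matrix(
    records: Sequence[Cdr3Record],
    ks: Iterable[int],
    subset: str | None = None,
    feature_space: FeatureSpace | None = None,
    row_unit: str = "sample",
    alphabet: str = AA_ALPHABET,
) -> KmerCountMatrix:
    """Aggregate k-mer occurrences into a zero-filled count matrix.

    Parameters
    ----------
    records:
        Annotated records (sample_id, subset, state populated).
    ks:
        k values; a single joint feature space over all of them is built
        unless ``feature_space`` is supplied.
    subset:
        If given, restrict to records of that cell subset.
    row_unit:
        "sample" aggregates per (sample_id, subset) repertoire (default);
        "cell" keeps one row per cell.

    Raises
    ------
    ValueError
        If a sample carries conflicting disease-state labels.
    """
    if row_unit not in {"sample", "cell"}:
        raise ValueError(f"row_unit must be 'sample' or 'cell', got {row_unit!r}")
    fs = feature_space or enumerate_feature_space(ks, alphabet)
    if subset is not None:
        records = [r for r in records if r.subset == subset]

    # one state per sample, regardless of row unit
    sample_states: dict[str, int] = {}
    for rec in records:
        prev = sample_states.setdefault(rec.sample_id, rec.state)
        if prev != rec.state:
            raise ValueError(
                f"sample {rec.sample_id!r} has conflicting state labels "
                f"({prev} vs {rec.state})"
            )

    row_index: dict[tuple[str, str], int] = {}
    row_keys: list[tuple[str, str]] = []
    labels: list[int] = []
    data: dict[tuple[int, int], int] = {}
    index = fs.index
    for rec in records:
        key = (
            (rec.sample_id, rec.subset)
            if row_unit == "sample"
            else (rec.cell_barcode, rec.subset)
        )
        r = row_index.get(key)
        if r is None:
            r = row_index[key] = len(row_keys)
            row_keys.append((str(key[0]), str(key[1])))
            labels.append(rec.state)
        seq = rec.cdr3aa
        for k in fs.ks:
            for i in range(len(seq) - k + 1):
                c = index.get(seq[i : i + k])
                # windows with non-alphabet characters are absent from the index
                if c is not None:
                    data[(r, c)] = data.get((r, c), 0) + 1

    if data:
        rows, cols = zip(*data)
        counts = sparse.coo_matrix(
            (list(data.values()), (rows, cols)),
            shape=(len(row_keys), fs.n_features),
            dtype=np.int64,
        ).tocsr()
    else:
        counts = sparse.csr_matrix((len(row_keys), fs.n_features), dtype=np.int64)
    return KmerCountMatrix(
        row_keys=row_keys,
        feature_space=fs,
        counts=counts,
        labels=np.asarray(labels, dtype=int),
    )


def combine_kmer_datasets(matrices: Sequence[KmerCountMatrix]) -> KmerCountMatrix:
    """Column-wise concatenation of count matrices over disjoint k-sets.

    Inputs must share row keys and labels; blocks are ordered by ascending k
    so the result matches ``enumerate_feature_space`` over the combined k-set.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    ordered = sorted(matrices, key=lambda m: m.feature_space.ks)
    first = ordered[0]
    all_ks: list[int] = []
    for m in ordered:
        if m.row_keys != first.row_keys:
            raise ValueError("row keys differ between matrices; cannot combine")
        if not np.array_equal(m.labels, first.labels):
            raise ValueError("labels differ between matrices; cannot combine")
        if set(m.feature_space.ks) & set(all_ks):
            raise ValueError("k values overlap between matrices")
        if m.feature_space.alphabet != first.feature_space.alphabet:
            raise ValueError("alphabets differ between matrices")
        all_ks.extend(m.feature_space.ks)
    columns = tuple(c for m in ordered for c in m.feature_space.columns)
    fs = FeatureSpace(
        ks=tuple(sorted(all_ks)),
        alphabet=first.feature_space.alphabet,
        columns=columns,
        index={c: i for i, c in enumerate(columns)},
    )
    counts = sparse.hstack([m.counts for m in ordered], format="csr")
    return KmerCountMatrix(
        row_keys=list(first.row_keys),
        feature_space=fs,
        counts=counts,
        labels=first.labels.copy(),
    )


def dataset_name(ks: Iterable[int]) -> str:
    """Canonical dataset name for a k-set, e.g. ``kmer2_3`` for {2, 3}."""
    return "kmer" + "_".join(str(k) for k in sorted(ks))


def seven_datasets(
    records: Sequence[Cdr3Record],
    ks: Iterable[int] = (2, 3, 4),
    subset: str | None = None,
    row_unit: str = "sample",
    alphabet: str = AA_ALPHABET,
) -> dict[str, KmerCountMatrix]:
    """One count matrix per non-empty subset of ``ks``.

    The default k-set {2, 3, 4} yields the seven datasets kmer2, kmer3,
    kmer4, kmer2_3, kmer2_4, kmer3_4, kmer2_3_4 (2^|ks| - 1 in general).
    Single-k matrices are counted once and combined by concatenation.
    """
    ks = tuple(sorted({int(k) for k in ks}))
    singles = {
        k: build_count_matrix(records, (k,), subset=subset, row_unit=row_unit,
                              alphabet=alphabet)
        for k in ks
    }
    out: dict[str, KmerCountMatrix] = {}
    for size in range(1, len(ks) + 1):
        for combo in combinations(ks, size):
            out[dataset_name(combo)] = combine_kmer_datasets([singles[k] for k in combo])
    return out
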