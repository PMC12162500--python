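"""Reading and joining immune-repertoire tables.

This module loads per-cell CDR3 amino-acid observations from
AIRR-rearrangement-style tables (``cell_id``, ``locus``, ``junction_aa``),
joins them with cell-level annotations (sample, cell subset, disease state)
on the cell barcode, and provides descriptive CDR3 length distributions.

The disease state is encoded as an integer class: 0 = healthy/normal,
1 = mild/moderate infection, 2 = severe infection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, lexicographically ordered.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Receptor chains handled by the pipeline: BCR heavy chain and TCR alpha chain.
CHAINS = ("BCRH", "TCRA")

#: Mapping from AIRR locus names (and already-canonical chain names) to chains.
LOCUS_TO_CHAIN = {
    "IGH": "BCRH",
    "TRA": "TCRA",
    "BCRH": "BCRH",
    "TCRA": "TCRA",
}

CHAIN_TO_LOCUS = {"BCRH": "IGH", "TCRA": "TRA"}

#: Accepted spellings of the three disease states.
STATE_LABELS = {
    "h": 0, "healthy": 0, "normal": 0, "0": 0,
    "m": 1, "mild": 1, "moderate": 1, "mild/moderate": 1, "1": 1,
    "s": 2, "severe": 2, "2": 2,
}

#: Short display names used in report tables, indexed by state code.
STATE_NAMES = {0: "H", 1: "M", 2: "S"}

#: Default source-column names (AIRR rearrangement schema).
DEFAULT_COLUMN_MAP = {
    "cell_barcode": "cell_id",
    "locus": "locus",
    "cdr3aa": "junction_aa",
}


def parse_state(value) -> int:
    """Map a state label (string or integer) to its class code 0/1/2."""
    key = str(value).strip().lower()
    if key not in STATE_LABELS:
        raise ValueError(
            f"unrecognized disease-state label {value!r}; "
            f"expected one of {sorted(set(STATE_LABELS))}"
        )
    return STATE_LABELS[key]


@dataclass(frozen=True)
class Cdr3Record:
    """One cell's receptor observation.

    ``sample_id``, ``subset`` and ``state`` are ``None`` until the record is
    joined with cell annotations (:func:`join_annotations`).
    """

    cell_barcode: str
    chain: str
    cdr3aa: str
    sample_id: str | None = None
    subset: str | None = None
    state: int | None = None


@dataclass
class LoadReport:
    """Row accounting for :func:`read_repertoire`."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_empty: int = 0
    n_dropped_chain: int = 0
    n_dropped_nonstandard: int = 0
    n_duplicate_cells: int = 0


@dataclass
class JoinReport:
    """Barcode accounting for :func:`join_annotations`."""

    n_records: int = 0
    n_joined: int = 0
    n_unmatched_records: int = 0
    n_unused_metadata: int = 0


@dataclass(frozen=True)
class LengthDistribution:
    """CDR3 length histogram for one group of records."""

    group: int
    counts: Mapping[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read repertoire table {path}: {exc}") from exc


def read_repertoire(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    chain: str | None = None,
    alphabet: str = AA_ALPHABET,
    strict: bool = False,
    first_entry_wins: bool = True,
) -> tuple[list[Cdr3Record], LoadReport]:
    """Read a delimited repertoire table into per-cell CDR3 records.

    Parameters
    ----------
    path:
        TSV/CSV file. Tab-separated for ``.tsv``/``.tab``/``.txt``, comma
        otherwise.
    column_map:
        Overrides for source column names, keyed by canonical name
        (``cell_barcode``, ``locus``, ``cdr3aa``). Defaults cover the AIRR
        rearrangement schema (``cell_id``, ``locus``, ``junction_aa``).
    chain:
        If given ("BCRH" or "TCRA"), keep only rows of that chain; rows of
        other or unknown loci are dropped and counted.
    strict:
        If True, drop records whose CDR3 contains characters outside
        ``alphabet``; otherwise keep them (k-mers spanning those characters
        are skipped downstream, so the feature space stays complete).
    first_entry_wins:
        Collapse multiple CDR3 entries for the same (barcode, chain) to the
        first row, counting the discarded duplicates.

    Returns
    -------
    (records, report):
        Cleaned records with uppercased CDR3, and a :class:`LoadReport` with
        drop counts.
    """
    if chain is not None and chain not in CHAINS:
        raise ValueError(f"chain must be one of {CHAINS}, got {chain!r}")
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    df = _read_table(path)
    for canonical in ("cell_barcode", "locus", "cdr3aa"):
        if colmap[canonical] not in df.columns:
            raise KeyError(
                f"repertoire table {path} is missing required column "
                f"{colmap[canonical]!r} (for {canonical!r}); available: "
                f"{list(df.columns)}"
            )

    report = LoadReport(n_rows=len(df))
    alpha = set(alphabet)
    seen: set[tuple[str, str]] = set()
    records: list[Cdr3Record] = []
    for barcode, locus, seq in zip(
        df[colmap["cell_barcode"]], df[colmap["locus"]], df[colmap["cdr3aa"]]
    ):
        if pd.isna(seq) or not str(seq).strip():
            report.n_dropped_empty += 1
            continue
        rec_chain = LOCUS_TO_CHAIN.get(str(locus).strip().upper())
        if rec_chain is None or (chain is not None and rec_chain != chain):
            report.n_dropped_chain += 1
            continue
        cdr3 = str(seq).strip().upper()
        if strict and not set(cdr3) <= alpha:
            report.n_dropped_nonstandard += 1
            continue
        key = (str(barcode), rec_chain)
        if first_entry_wins and key in seen:
            report.n_duplicate_cells += 1
            continue
        seen.add(key)
        records.append(Cdr3Record(str(barcode), rec_chain, cdr3))
    report.n_loaded = len(records)
    logger.info(
        "read %d rows from %s: %d loaded, %d empty, %d off-chain, %d duplicates",
        report.n_rows, path, report.n_loaded, report.n_dropped_empty,
        report.n_dropped_chain, report.n_duplicate_cells,
    )
    return records, report


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cell-annotation table with columns barcode,sample_id,subset,state."""
    df = _read_table(path)
    missing = {"barcode", "sample_id", "subset", "state"} - set(df.columns)
    if missing:
        raise KeyError(f"metadata {path} is missing columns {sorted(missing)}")
    return df


def join_annotations(
    records: Sequence[Cdr3Record],
    metadata: pd.DataFrame | str | Path,
) -> tuple[list[Cdr3Record], JoinReport]:
    """Inner-join CDR3 records with cell annotations on the cell barcode.

    ``metadata`` is a table (or path to one) with columns
    ``barcode, sample_id, subset, state``; state labels are parsed with
    :func:`parse_state`. Only barcodes present in both inputs survive.

    Raises
    ------
    ValueError
        If the metadata contains duplicate barcodes.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    dupes = metadata["barcode"][metadata["barcode"].duplicated()].unique()
    if len(dupes):
        shown = ", ".join(map(str, dupes[:10]))
        raise ValueError(
            f"metadata contains {len(dupes)} duplicate barcode(s): {shown}"
            + (" ..." if len(dupes) > 10 else "")
        )
    lookup = {
        str(row.barcode): (str(row.sample_id), str(row.subset), parse_state(row.state))
        for row in metadata.itertuples(index=False)
    }
    report = JoinReport(n_records=len(records))
    joined: list[Cdr3Record] = []
    hit_barcodes: set[str] = set()
    for rec in records:
        ann = lookup.get(rec.cell_barcode)
        if ann is None:
            report.n_unmatched_records += 1
            continue
        sample_id, subset, state = ann
        hit_barcodes.add(rec.cell_barcode)
        joined.append(
            Cdr3Record(rec.cell_barcode, rec.chain, rec.cdr3aa,
                       sample_id=sample_id, subset=subset, state=state)
        )
    report.n_joined = len(joined)
    report.n_unused_metadata = len(lookup) - len(hit_barcodes)
    if not joined:
        logger.warning("join produced no records (no shared barcodes)")
    logger.info(
        "joined %d/%d records; %d metadata barcodes unused",
        report.n_joined, report.n_records, report.n_unused_metadata,
    )
    return joined, report


def dedupe_clonotypes(records: Sequence[Cdr3Record]) -> list[Cdr3Record]:
    """Collapse records sharing (sample, subset, chain, CDR3) to one per clonotype.

    The default pipeline counts k-mers once per cell; this offers the
    per-clonotype alternative.
    """
    seen: set[tuple] = set()
    out: list[Cdr3Record] = []
    for rec in records:
        key = (rec.sample_id, rec.subset, rec.chain, rec.cdr3aa)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def length_distribution(
    records: Sequence[Cdr3Record], by: str = "state"
) -> list[LengthDistribution]:
    """CDR3 length histograms per group (default grouping: disease state)."""
    groups: dict = {}
    for rec in records:
        key = getattr(rec, by)
        groups.setdefault(key, {})
        length = len(rec.cdr3aa)
        groups[key][length] = groups[key].get(length, 0) + 1
    return [
        LengthDistribution(group=key, counts=dict(sorted(counts.items())))
        for key, counts in sorted(groups.items(), key=lambda kv: str(kv[0]))
    ]


def distributions_to_frame(dists: Iterable[LengthDistribution]) -> pd.DataFrame:
    """Tidy (group, length, count) table, ready for CSV export or plotting."""
    rows = [
        {"group": d.group, "length": length, "count": count}
        for d in dists
        for length, count in d.counts.items()
    ]
    return pd.DataFrame(rows, columns=["group", "length", "count"])


def records_to_frame(records: Sequence[Cdr3Record]) -> pd.DataFrame:
    """Records as a DataFrame (one row per cell)."""
    return pd.DataFrame(
        [
            {
                "cell_barcode": r.cell_barcode,
                "chain": r.chain,
                "cdr3aa": r.cdr3aa,
                "sample_id": r.sample_id,
                "subset": r.subset,
                "state": r.state,
            }
            for r in records
        ],
        columns=["cell_barcode", "chain", "cdr3aa", "sample_id", "subset", "state"],
    )
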