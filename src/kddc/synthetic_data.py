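"""Synthetic CDR3 repertoires with controllable class signal.

The generator emulates the statistical structure the classifier is meant to
detect: per-class usage of short amino-acid motifs embedded in otherwise
background CDR3 sequences. Each cell's CDR3 is drawn letter-by-letter from a
background composition with a length sampled from a configurable
distribution; for cells of a class that carries motifs, one motif is chosen
uniformly and, with that motif's insertion probability, written over a
uniformly placed window of the sequence. Overwriting (rather than inserting)
keeps the length distribution identical across classes, so any class signal
is purely compositional.

Defaults model a three-state cohort (healthy / mild / severe) of 30 samples
per state with 200 cells per sample, and three 3-mer motifs in each
non-healthy state at insertion probability 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .feature_select import SelectionResult
from .kmer_features import FeatureSpace
from .repertoire_io import AA_ALPHABET, CHAIN_TO_LOCUS, Cdr3Record, records_to_frame

__all__ = [
    "SimConfig",
    "TruthManifest",
    "generate_repertoire",
    "write_repertoire",
    "truth_recovery_check",
]

#: Default planted motifs: three 3-mers per non-healthy state.
DEFAULT_CLASS_MOTIFS: dict[int, tuple[tuple[str, float], ...]] = {
    1: (("DLW", 0.9), ("FDL", 0.9), ("YDY", 0.9)),
    2: (("RGG", 0.9), ("GGF", 0.9), ("EQY", 0.9)),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``class_motifs`` maps a state code to (motif, insertion_prob) pairs; for
    each motif-carrying cell one motif of its class is chosen uniformly and
    applied with that motif's probability. ``subset_motifs`` optionally
    overrides the motif table per cell subset.
    """

    n_samples_per_class: int = 30
    cells_per_sample: int = 200
    length_dist: Mapping[int, float] | None = None  # default: uniform on 8..20
    class_motifs: Mapping[int, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MOTIFS)
    )
    background: Mapping[str, float] | None = None  # default: uniform over alphabet
    subsets: tuple[str, ...] = ("sim",)
    subset_motifs: Mapping[str, Mapping[int, Sequence[tuple[str, float]]]] | None = None
    classes: tuple[int, ...] = (0, 1, 2)
    chain: str = "BCRH"
    alphabet: str = AA_ALPHABET
    seed: int = 0

    def resolved_length_dist(self) -> tuple[np.ndarray, np.ndarray]:
        dist = self.length_dist or {L: 1 / 13 for L in range(8, 21)}
        lengths = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[int(L)] for L in lengths], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("length_dist probabilities must sum to 1")
        return lengths, probs / probs.sum()

    def resolved_background(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(self.alphabet), 1.0 / len(self.alphabet))
        probs = np.array([self.background.get(a, 0.0) for a in self.alphabet])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        return probs / probs.sum()

    def motifs_for(self, subset: str) -> Mapping[int, Sequence[tuple[str, float]]]:
        if self.subset_motifs is not None and subset in self.subset_motifs:
            return self.subset_motifs[subset]
        return self.class_motifs

    def validate(self) -> None:
        lengths, _ = self.resolved_length_dist()
        max_len = int(lengths.max())
        for subset in self.subsets:
            for state, motifs in self.motifs_for(subset).items():
                if state not in self.classes:
                    raise ValueError(f"motif state {state} not in classes {self.classes}")
                for motif, prob in motifs:
                    if not 0.0 <= prob <= 1.0:
                        raise ValueError(f"insertion_prob {prob} outside [0, 1]")
                    if len(motif) > max_len:
                        raise ValueError(
                            f"motif {motif!r} longer than the maximum CDR3 length {max_len}"
                        )
                    if not set(motif) <= set(self.alphabet):
                        raise ValueError(f"motif {motif!r} uses letters outside the alphabet")


@dataclass
class TruthManifest:
    """Record of every planted motif, per subset and state."""

    motifs: dict[str, dict[int, list[str]]]

    def planted_motifs(self, subset: str | None = None) -> list[str]:
        """Unique planted motifs (across states), optionally for one subset."""
        out: list[str] = []
        for sub, per_state in self.motifs.items():
            if subset is not None and sub != subset:
                continue
            for state in sorted(per_state):
                for m in per_state[state]:
                    if m not in out:
                        out.append(m)
        return out

    def to_json(self) -> str:
        payload = {
            sub: {str(state): motifs for state, motifs in per_state.items()}
            for sub, per_state in self.motifs.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _sample_cdr3(rng, lengths, length_probs, bg, alphabet_arr, motifs, min_resample=100):
    """One CDR3 string; motifs is a list of (motif, prob) or empty."""
    motif = None
    if motifs:
        motif, prob = motifs[rng.integers(len(motifs))]
        if rng.random() >= prob:
            motif = None
    length = int(lengths[rng.choice(len(lengths), p=length_probs)])
    if motif is not None and len(motif) > length:
        for _ in range(min_resample):
            length = int(lengths[rng.choice(len(lengths), p=length_probs)])
            if len(motif) <= length:
                break
        else:
            raise ValueError(
                f"could not sample a CDR3 length >= len({motif!r}) in "
                f"{min_resample} attempts"
            )
    letters = alphabet_arr[rng.choice(len(alphabet_arr), size=length, p=bg)]
    if motif is not None:
        off = int(rng.integers(0, length - len(motif) + 1))
        letters[off : off + len(motif)] = list(motif)
    return "".join(letters)


def generate_repertoire(config: SimConfig) -> tuple[list[Cdr3Record], TruthManifest]:
    """Generate per-cell CDR3 records plus the planted-motif manifest.

    Fully reproducible under ``config.seed``. Sample IDs encode the state
    (``s<state>_<i>``); cells are split evenly across the configured subsets
    within each sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths, length_probs = config.resolved_length_dist()
    bg = config.resolved_background()
    alphabet_arr = np.array(list(config.alphabet))

    records: list[Cdr3Record] = []
    for state in config.classes:
        for i in range(config.n_samples_per_class):
            sample_id = f"s{state}_{i:02d}"
            for s_idx, subset in enumerate(config.subsets):
                n_cells = config.cells_per_sample // len(config.subsets)
                if s_idx < config.cells_per_sample % len(config.subsets):
                    n_cells += 1
                motifs = list(config.motifs_for(subset).get(state, ()))
                for j in range(n_cells):
                    cdr3 = _sample_cdr3(rng, lengths, length_probs, bg,
                                        alphabet_arr, motifs)
                    records.append(
                        Cdr3Record(
                            cell_barcode=f"c-{sample_id}-{subset}-{j:04d}",
                            chain=config.chain,
                            cdr3aa=cdr3,
                            sample_id=sample_id,
                            subset=subset,
                            state=int(state),
                        )
                    )
    manifest = TruthManifest(
        motifs={
            subset: {
                int(state): [m for m, _ in config.motifs_for(subset).get(state, ())]
                for state in config.classes
                if config.motifs_for(subset).get(state)
            }
            for subset in config.subsets
        }
    )
    return records, manifest


def write_repertoire(
    records: Sequence[Cdr3Record],
    out_dir: str | Path,
    truth: TruthManifest | None = None,
) -> dict[str, Path]:
    """Emit AIRR-style repertoire TSV + metadata CSV (+ truth JSON).

    The files round-trip through :func:`kddc.repertoire_io.read_repertoire`
    and :func:`kddc.repertoire_io.join_annotations`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    rep = frame[["cell_barcode", "chain", "cdr3aa"]].copy()
    rep.columns = ["cell_id", "locus", "junction_aa"]
    rep["locus"] = rep["locus"].map(CHAIN_TO_LOCUS)
    rep_path = out_dir / "repertoire.tsv"
    rep.to_csv(rep_path, sep="\t", index=False)

    meta = frame[["cell_barcode", "sample_id", "subset", "state"]].copy()
    meta.columns = ["barcode", "sample_id", "subset", "state"]
    meta_path = out_dir / "metadata.csv"
    meta.to_csv(meta_path, index=False)

    paths = {"repertoire": rep_path, "metadata": meta_path}
    if truth is not None:
        truth_path = out_dir / "truth.json"
        truth_path.write_text(truth.to_json() + "\n")
        paths["truth"] = truth_path
    return paths


def truth_recovery_check(
    selection: SelectionResult,
    truth: TruthManifest,
    feature_space: FeatureSpace,
    top_n: int = 20,
    subset: str | None = None,
) -> float:
    """Fraction of planted motifs among the ``top_n`` features ranked by F.

    Only motifs whose length is one of the feature space's k values are
    scored (others cannot appear as exact k-mer features).
    """
    motifs = [
        m for m in truth.planted_motifs(subset) if len(m) in feature_space.ks
    ]
    if not motifs:
        raise ValueError("no planted motifs are representable in this feature space")
    f = np.where(np.isfinite(selection.f_stat), selection.f_stat, -np.inf)
    order = np.argsort(-f, kind="stable")[:top_n]
    top = {feature_space.columns[i] for i in order}
    return sum(m in top for m in motifs) / len(motifs)
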