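import numpy as np
import pytest

from kddc.repertoire_io import Cdr3Record
from kddc.synthetic_data import SimConfig, generate_repertoire


def make_records(seqs_by_sample, subset="B_c1", chain="BCRH", states=None):
    """Hand-rolled annotated records: {sample: [cdr3, ...]} -> list[Cdr3Record]."""
    states = states or {}
    records = []
    for sample, seqs in seqs_by_sample.items():
        for j, seq in enumerate(seqs):
            records.append(
                Cdr3Record(
                    cell_barcode=f"{sample}-{j}",
                    chain=chain,
                    cdr3aa=seq,
                    sample_id=sample,
                    subset=subset,
                    state=states.get(sample, 0),
                )
            )
    return records


def naive_kmer_counts(seqs, ks, alphabet):
    """Independent dictionary-count oracle for overlapping k-mer windows."""
    counts: dict[str, int] = {}
    alpha = set(alphabet)
    for seq in seqs:
        for k in ks:
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if set(window) <= alpha:
                    counts[window] = counts.get(window, 0) + 1
    return counts


def f_oneway_oracle(x, labels):
    """Direct sums-of-squares one-way ANOVA for a single feature vector."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    groups = [x[labels == g] for g in np.unique(labels)]
    n, g = len(x), len(groups)
    grand = x.mean()
    ss_between = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    ss_within = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    df_b, df_w = g - 1, n - g
    return (ss_between / df_b) / (ss_within / df_w), (df_b, df_w)


def auc_concordance_oracle(pos_scores, neg_scores):
    """Binary AUC by counting concordant pairs (ties count one half)."""
    pairs = [(p, n) for p in pos_scores for n in neg_scores]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in pairs)
    return wins / len(pairs)


@pytest.fixture(scope="session")
def default_benchmark():
    """One repertoire at the generator's default study conditions."""
    return generate_repertoire(SimConfig(seed=20260927))


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced repertoire for classifier tests (same structure, faster)."""
    config = SimConfig(n_samples_per_class=15, cells_per_sample=60, seed=7)
    return generate_repertoire(config), config
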