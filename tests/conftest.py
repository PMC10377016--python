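import numpy as np
import pandas as pd
import pytest

import trnachip as t

# The nine initiator-methionine genes: eight identical-sequence copies in
# isodecoder family 1 plus the divergent family-2 singleton.
IMET_GENE_IDS = [f"tRNA-iMet-CAT-1-{i}" for i in range(1, 9)] + ["tRNA-iMet-CAT-2-1"]


@pytest.fixture(scope="session")
def imet_records():
    return [
        t.TRNAGeneRecord(gene_id=gid, chrom="chr6", start=10_000 * (i + 1),
                         end=10_000 * (i + 1) + 72)
        for i, gid in enumerate(IMET_GENE_IDS)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config synthetic cohort, shared across tests."""
    cfg = t.SyntheticConfig(seed=11)
    cohort = t.simulate_chip_cohort(cfg)
    return cfg, cohort


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    cfg, cohort = default_cohort
    return t.build_signal_matrix(
        cohort.sheet, cohort.annotation, chrom_lengths=cohort.chrom_lengths
    )


def brute_force_counts(fragments: pd.DataFrame, windows) -> np.ndarray:
    """Exhaustive all-pairs overlap oracle (half-open intervals)."""
    counts = np.zeros(len(windows), dtype=int)
    rows = list(fragments.itertuples(index=False))
    for i, win in enumerate(windows):
        counts[i] = sum(
            1 for chrom, start, end in rows
            if chrom == win.chrom and start < win.end and end > win.start
        )
    return counts


def random_instance(rng, n_frags, n_windows, n_chroms=3, span=10_000):
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    starts = rng.integers(0, span, size=n_frags)
    lengths = rng.integers(1, 400, size=n_frags)
    frags = pd.DataFrame({
        "chrom": rng.choice(chroms, size=n_frags),
        "start": starts,
        "end": starts + lengths,
    })
    windows = []
    for _ in range(n_windows):
        s = int(rng.integers(0, span))
        w = int(rng.integers(1, 1_500))
        windows.append(t.GenomicWindow(str(rng.choice(chroms)), s, s + w))
    return frags, windows
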