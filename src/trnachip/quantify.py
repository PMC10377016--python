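"""Window signal quantification: fragments → counts → RPM → input-normalized Q.

The quantification follows standard fixed-window ChIP-seq practice: for each
gene a ±flank window around the gene centre is scanned for overlapping DNA
fragments (any-overlap by default), counts are scaled to fragments per
million, and the ChIP value is divided by the matched input control. The
resulting per-gene, per-sample ratio is the "Q-value" used by all downstream
analyses. Cells whose input coverage is too thin to normalize reliably are
recorded as missing with a reason code (rendered grey in heat maps).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicWindow, TRNAGeneRecord, sort_by_position, window_of

log = logging.getLogger(__name__)

ReadMode = Literal["paired_fragment", "single_end_extended"]

#: Missing-cell reason codes
REASON_INADEQUATE_INPUT = "inadequate input"
REASON_ZERO_INPUT = "division by zero input"
REASON_NO_FRAGMENTS = "no fragments in library"

CONDITION_ORDER = {"primary": 0, "metastatic": 1, "other": 2}


@dataclass
class FragmentSource:
    """One sample's fragment evidence: a SAM/BAM/BED path or an in-memory frame.

    ``frame`` (columns chrom, start, end; 0-based half-open) takes precedence
    over ``path``. For alignments, ``read_mode`` controls how a fragment
    interval is derived: ``paired_fragment`` uses the template span between
    mates; ``single_end_extended`` extends each read to ``fragment_length``
    from its 5' end. ``library_size`` defaults to the number of fragments
    surviving the alignment filters, computed once; it may be overridden for
    reproducibility.
    """

    sample_id: str
    path: str | Path | None = None
    frame: pd.DataFrame | None = None
    read_mode: ReadMode = "paired_fragment"
    fragment_length: int = 200
    library_size: int | None = None
    drop_duplicates: bool = True
    _cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def fragments(self) -> pd.DataFrame:
        """Load (and cache) the fragment intervals."""
        if self._cache is None:
            if self.frame is not None:
                frags = self.frame[["chrom", "start", "end"]].reset_index(drop=True)
            elif self.path is None:
                raise ValueError(f"{self.sample_id}: no path or frame supplied")
            else:
                frags = _read_fragments(
                    Path(self.path), self.read_mode, self.fragment_length,
                    self.drop_duplicates,
                )
            self._cache = frags
        return self._cache

    def effective_library_size(self) -> int:
        return self.library_size if self.library_size is not None else len(self.fragments())


def _read_fragments(
    path: Path, read_mode: ReadMode, fragment_length: int, drop_duplicates: bool
) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".bed", ".bedgraph", ".txt", ".tsv"}:
        frags = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return frags.astype({"start": np.int64, "end": np.int64})
    if suffix in {".sam", ".bam", ".cram"}:
        return _read_alignment_fragments(path, read_mode, fragment_length, drop_duplicates)
    raise ValueError(f"cannot infer fragment format from suffix {suffix!r} ({path})")


def _read_alignment_fragments(
    path: Path, read_mode: ReadMode, fragment_length: int, drop_duplicates: bool
) -> pd.DataFrame:
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            if read_mode == "paired_fragment":
                # Count each template once, from the leftmost mate.
                if not read.is_paired or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                if read.is_reverse:
                    end = read.reference_end
                    start = max(0, end - fragment_length)
                else:
                    start = read.reference_start
                    end = start + fragment_length
            chroms.append(read.reference_name)
            starts.append(start)
            ends.append(end)
    return pd.DataFrame(
        {"chrom": chroms,
         "start": np.asarray(starts, dtype=np.int64),
         "end": np.asarray(ends, dtype=np.int64)}
    )


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------

def count_fragments_in_windows(
    source: FragmentSource | pd.DataFrame,
    windows: Sequence[GenomicWindow],
    mode: Literal["any_overlap", "midpoint"] = "any_overlap",
) -> np.ndarray:
    """Count fragments intersecting each window.

    ``any_overlap`` counts fragments sharing >=1 bp with the window (a
    fragment spanning several windows is counted in each); ``midpoint``
    counts a fragment only in the window containing its midpoint. All
    intervals are half-open, so an abutting fragment does not count.

    Counting is order-independent in both fragments and windows; a window on
    a chromosome absent from the source gets count 0 with a warning.
    """
    frags = source.fragments() if isinstance(source, FragmentSource) else source
    counts = np.zeros(len(windows), dtype=np.int64)
    if len(frags) == 0:
        return counts
    if mode == "midpoint":
        mid = (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
        frags = pd.DataFrame({"chrom": frags["chrom"], "start": mid, "end": mid + 1})
    elif mode != "any_overlap":
        raise ValueError(f"unknown counting mode {mode!r}")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in frags.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            np.sort(sub["start"].to_numpy(np.int64)),
            np.sort(sub["end"].to_numpy(np.int64)),
        )
    missing_chroms: set[str] = set()
    for i, win in enumerate(windows):
        pair = by_chrom.get(win.chrom)
        if pair is None:
            missing_chroms.add(win.chrom)
            continue
        starts, ends = pair
        n = starts.size
        # overlap <=> frag.start < win.end and frag.end > win.start; the two
        # excluded sets are disjoint because every fragment has start < end.
        n_right = n - np.searchsorted(starts, win.end, side="left")
        n_left = np.searchsorted(ends, win.start, side="right")
        counts[i] = n - n_right - n_left
    if missing_chroms:
        log.warning(
            "windows on chromosome(s) %s absent from fragment source; counts set to 0",
            ", ".join(sorted(missing_chroms)),
        )
    return counts


def to_rpm(counts: np.ndarray | Sequence[float], library_size: float) -> np.ndarray:
    """Fragments-per-million scaling: count × 10⁶ / library_size."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def input_normalize(
    chip_rpm: np.ndarray | Sequence[float],
    input_rpm: np.ndarray | Sequence[float],
    pseudocount: float = 0.5,
    input_raw: np.ndarray | Sequence[float] | None = None,
    min_input: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """ChIP/input ratio per window, with missingness for thin input.

    Q = chip_rpm / (input_rpm + pseudocount), with the pseudocount on the RPM
    scale so that Q is invariant under whole-library duplication. A cell is
    missing (NaN, with a reason) when the *raw* input coverage falls below
    ``min_input`` fragments, or when pseudocount and input are both zero.
    Returns ``(q, reasons)`` where reasons is an object array (None where ok).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    chip_rpm = np.asarray(chip_rpm, dtype=float)
    input_rpm = np.asarray(input_rpm, dtype=float)
    q = np.full(chip_rpm.shape, np.nan)
    reasons = np.full(chip_rpm.shape, None, dtype=object)
    denom = input_rpm + pseudocount
    zero_div = denom == 0
    reasons[zero_div] = REASON_ZERO_INPUT
    ok = ~zero_div
    if input_raw is not None:
        thin = np.asarray(input_raw, dtype=float) < min_input
        reasons[thin & ~zero_div] = REASON_INADEQUATE_INPUT
        ok &= ~thin
    q[ok] = chip_rpm[ok] / denom[ok]
    return q, reasons


# ---------------------------------------------------------------------------
# Sample sheets and the signal matrix
# ---------------------------------------------------------------------------

@dataclass
class SampleRow:
    sample_id: str
    condition: str  # primary | metastatic | other
    chip: FragmentSource
    input: FragmentSource


@dataclass
class SampleSheet:
    """ChIP/input pairing per sample, with a condition label."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def conditions(self) -> dict[str, str]:
        return {r.sample_id: r.condition for r in self.rows}

    def ordered(self) -> list[SampleRow]:
        """Primary samples first, then metastatic, then other (stable)."""
        return sorted(
            self.rows, key=lambda r: CONDITION_ORDER.get(r.condition, 3)
        )


def read_sample_sheet(
    path: str | Path,
    base_dir: str | Path | None = None,
    read_mode: ReadMode = "paired_fragment",
) -> SampleSheet:
    """Read a delimited sheet with header (sample_id, condition, chip, input)."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "chip", "input"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"sample sheet must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    rows = []
    for rec in table.itertuples(index=False):
        rows.append(
            SampleRow(
                sample_id=str(rec.sample_id),
                condition=str(rec.condition),
                chip=FragmentSource(
                    f"{rec.sample_id}_chip", path=base / str(rec.chip),
                    read_mode=read_mode,
                ),
                input=FragmentSource(
                    f"{rec.sample_id}_input", path=base / str(rec.input),
                    read_mode=read_mode,
                ),
            )
        )
    return SampleSheet(rows)


@dataclass
class SignalMatrix:
    """Genes × samples matrix of window signal with per-cell missing reasons.

    ``values`` holds floats with NaN for missing cells; ``reasons`` is an
    aligned object frame holding a reason string wherever a cell is missing.
    ``stage`` records the normalization state (raw_count, rpm,
    input_normalized); ``meta`` carries provenance such as library sizes.
    """

    values: pd.DataFrame
    reasons: pd.DataFrame | None = None
    stage: str = "input_normalized"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        if self.reasons is None:
            self.reasons = pd.DataFrame(
                None, index=self.values.index, columns=self.values.columns,
                dtype=object,
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signal values must be non-negative")
        nan_mask = self.values.isna()
        unexplained = nan_mask & self.reasons.isna()
        if unexplained.any().any():
            raise ValueError("every missing cell needs a reason code")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path, reasons_path: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if reasons_path is not None:
            long = (
                self.reasons.stack().rename("reason").rename_axis(
                    ["gene_id", "sample_id"]
                ).reset_index()
            )
            long.to_csv(reasons_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "input_normalized") -> "SignalMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        reasons = pd.DataFrame(
            None, index=values.index, columns=values.columns, dtype=object
        )
        reasons[values.isna()] = "missing in file"
        return cls(values=values, reasons=reasons, stage=stage)


def build_signal_matrix(
    sheet: SampleSheet,
    genes: Sequence[TRNAGeneRecord],
    flank: int = 500,
    pseudocount: float = 0.5,
    min_input: int = 5,
    chrom_lengths: Mapping[str, int] | None = None,
    counting_mode: Literal["any_overlap", "midpoint"] = "any_overlap",
) -> SignalMatrix:
    """Run the full quantification for every sample in the sheet.

    Rows are genes in genomic order; columns are samples ordered primary
    then metastatic. A sample whose ChIP library is empty yields an
    all-missing column rather than an error.
    """
    genes = sort_by_position(genes)
    windows = [
        window_of(g, flank=flank,
                  chrom_length=chrom_lengths.get(g.chrom) if chrom_lengths else None)
        for g in genes
    ]
    rows = sheet.ordered()
    gene_ids = [g.gene_id for g in genes]
    values = pd.DataFrame(index=gene_ids, columns=[r.sample_id for r in rows],
                          dtype=float)
    reasons = pd.DataFrame(None, index=gene_ids, columns=values.columns, dtype=object)
    library_sizes: dict[str, dict[str, int]] = {}
    for row in rows:
        chip_n = row.chip.effective_library_size()
        input_n = row.input.effective_library_size()
        library_sizes[row.sample_id] = {"chip": chip_n, "input": input_n}
        if chip_n == 0 or input_n == 0:
            reasons[row.sample_id] = REASON_NO_FRAGMENTS
            continue
        chip_counts = count_fragments_in_windows(row.chip, windows, mode=counting_mode)
        input_counts = count_fragments_in_windows(row.input, windows, mode=counting_mode)
        q, why = input_normalize(
            to_rpm(chip_counts, chip_n),
            to_rpm(input_counts, input_n),
            pseudocount=pseudocount,
            input_raw=input_counts,
            min_input=min_input,
        )
        values[row.sample_id] = q
        reasons[row.sample_id] = why
    log.info(
        "build_signal_matrix: %d genes x %d samples; library sizes: %s",
        len(gene_ids), len(rows), library_sizes,
    )
    return SignalMatrix(
        values=values, reasons=reasons, stage="input_normalized",
        meta={
            "library_sizes": library_sizes,
            "flank": flank,
            "pseudocount": pseudocount,
            "min_input": min_input,
            "conditions": sheet.conditions(),
        },
    )
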