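"""Synthetic cohorts with conserved family budgets and heterogeneous members.

The generator emulates the statistical structure the analysis is built to
detect: each isoacceptor family has an activity budget that is nearly
conserved across tumours (log-normal with small between-sample spread),
while the *division* of that budget among member genes is drawn
independently per tumour from a Dirichlet with small concentration — so
different tumours activate different members of the same family. Summing
over families recovers stable totals; individual genes look erratic. A
matched input track, a sample sheet, and survival cohorts whose hazard
depends on one chosen unit's expression complete the inputs the pipeline
consumes, and every hidden parameter is returned as ground truth for
recovery tests.

All randomness flows from a single seeded :class:`numpy.random.Generator`;
identical configs reproduce outputs exactly, byte-for-byte on disk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TRNAGeneRecord, serialize_gene_name, window_of
from .quantify import FragmentSource, SampleRow, SampleSheet
from .survival import SurvivalTable, administrative_censor

log = logging.getLogger(__name__)

#: Amino-acid isotype labels used for toy annotations (standard isotypes
#: plus the initiator methionine).
ISOTYPE_LABELS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "iMet", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val", "SeC", "Sup", "Und",
)

#: Families-per-isotype size pattern, cycled until ``n_families`` is
#: consumed. Deliberately uneven, mirroring the skewed number of anticodon
#: families per amino acid in the human gene set (a few isotypes pool many
#: families, several have just one); the unevenness is what makes isotype
#: totals rank-stable across samples.
ISOTYPE_SIZE_PATTERN = (5, 4, 4, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1)


@dataclass
class SyntheticConfig:
    """All knobs of the generator, with study-condition defaults.

    The cohort defaults are 12 tumours (8 primary + 4 metastatic) over 40
    isoacceptor families of 5 genes each; ``sigma_budget`` is the
    between-sample SD of a family's log budget (small: budgets are nearly
    conserved) and ``alpha_sel`` the Dirichlet concentration governing how
    unevenly the budget is split among members (<1: a few members dominate,
    differing per tumour).
    """

    seed: int = 0
    # cohort
    n_primary: int = 8
    n_metastatic: int = 4
    # annotation
    n_families: int = 40
    members_per_family: int = 5
    gene_length: int = 72
    gene_spacing: int = 5000
    n_chromosomes: int = 4
    flank: int = 500
    # signal model
    family_budget_log_mean: float = math.log(500.0)
    family_budget_log_sd: float = 0.4     # spread of mean budgets across families
    sigma_budget: float = 0.15            # between-sample budget fluctuation
    alpha_sel: float = 0.3                # member-selection Dirichlet concentration
    met_shift_sd: float = 0.0             # optional per-family metastatic log-shift
    background_per_kb: float = 2.0        # ChIP off-target fragments per kb
    input_per_kb: float = 20.0            # input coverage per kb
    fragment_length: int = 200
    # survival model
    n_patients: int = 500
    effect_unit: str | None = None
    beta_true: float = 0.6
    baseline_hazard: float = 0.3          # events per year at mean expression
    censoring_fraction: float = 0.3
    horizon_years: float | None = 5.0

    def __post_init__(self) -> None:
        positive = {
            "n_primary": self.n_primary, "n_metastatic": self.n_metastatic,
            "n_families": self.n_families,
            "members_per_family": self.members_per_family,
            "gene_length": self.gene_length, "gene_spacing": self.gene_spacing,
            "n_chromosomes": self.n_chromosomes, "flank": self.flank,
            "alpha_sel": self.alpha_sel, "n_patients": self.n_patients,
            "baseline_hazard": self.baseline_hazard,
            "fragment_length": self.fragment_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.sigma_budget < 0:
            raise ValueError("sigma_budget must be >= 0")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_primary + self.n_metastatic

    @property
    def n_genes(self) -> int:
        return self.n_families * self.members_per_family


@dataclass
class SyntheticTruth:
    """Hidden parameters of a simulated cohort, for recovery tests."""

    family_log_means: pd.Series | None = None        # mu_f per family key
    budgets: pd.DataFrame | None = None              # families x samples A_{f,s}
    member_weights: pd.DataFrame | None = None       # genes x samples w_{g,s}
    expected_rates: pd.DataFrame | None = None       # genes x samples
    beta_true: float | None = None
    risk_scores: pd.Series | None = None             # per patient

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        if self.budgets is not None:
            self.budgets.to_csv(out / "truth_family_budgets.tsv", sep="\t",
                                index_label="family")
        if self.member_weights is not None:
            self.member_weights.to_csv(out / "truth_member_weights.tsv", sep="\t",
                                       index_label="gene_id")
        if self.expected_rates is not None:
            self.expected_rates.to_csv(out / "truth_expected_rates.tsv", sep="\t",
                                       index_label="gene_id")
        if self.risk_scores is not None:
            frame = self.risk_scores.rename("risk_score").to_frame()
            frame["beta_true"] = self.beta_true
            frame.to_csv(out / "truth_survival.tsv", sep="\t",
                         index_label="patient_id")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _isotype_plan(n_families: int) -> list[tuple[str, int]]:
    """Assign family counts to isotype labels by cycling the size pattern."""
    plan: list[tuple[str, int]] = []
    remaining = n_families
    i = 0
    while remaining > 0:
        label = ISOTYPE_LABELS[i % len(ISOTYPE_LABELS)]
        if i >= len(ISOTYPE_LABELS):  # more isotypes needed than labels exist
            label = f"{label}{i // len(ISOTYPE_LABELS) + 1}"
        size = min(ISOTYPE_SIZE_PATTERN[i % len(ISOTYPE_SIZE_PATTERN)], remaining)
        plan.append((label, size))
        remaining -= size
        i += 1
    return plan


def _anticodon_stream():
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                yield a + b + c


def make_annotation(config: SyntheticConfig) -> list[TRNAGeneRecord]:
    """Toy genome: well-formed gene names on evenly spaced, non-overlapping loci.

    Families are laid out round-robin across ``n_chromosomes`` toy
    chromosomes with ``gene_spacing`` bp between gene starts, so that
    ±flank windows never overlap. Within each isoacceptor family of m
    genes, members split into isodecoder family 1 (copies 1..m−1) plus a
    singleton family 2 — echoing the real pattern of one large
    identical-sequence family with a divergent extra locus.
    """
    if config.gene_spacing <= 2 * config.flank + config.gene_length:
        raise ValueError(
            "gene_spacing too small: windows would overlap; increase "
            "gene_spacing (or use longer chromosomes)"
        )
    anticodons = _anticodon_stream()
    records: list[TRNAGeneRecord] = []
    positions = {f"chr{i + 1}": config.gene_spacing for i in range(config.n_chromosomes)}
    chrom_cycle = list(positions)
    gi = 0
    for isotype, n_fams in _isotype_plan(config.n_families):
        for _ in range(n_fams):
            anticodon = next(anticodons)
            m = config.members_per_family
            if m >= 3:
                members = [(1, c) for c in range(1, m)] + [(2, 1)]
            else:
                members = [(1, c) for c in range(1, m + 1)]
            for fam, copy in members:
                chrom = chrom_cycle[gi % len(chrom_cycle)]
                start = positions[chrom]
                positions[chrom] += config.gene_spacing
                name = serialize_gene_name(isotype, anticodon, fam, copy)
                records.append(
                    TRNAGeneRecord(
                        gene_id=name, chrom=chrom, start=start,
                        end=start + config.gene_length,
                        strand="+" if gi % 2 == 0 else "-",
                    )
                )
                gi += 1
    return records


def chromosome_lengths(
    config: SyntheticConfig, records: Sequence[TRNAGeneRecord]
) -> dict[str, int]:
    lengths: dict[str, int] = {f"chr{i + 1}": 2 * config.gene_spacing
                               for i in range(config.n_chromosomes)}
    for rec in records:
        lengths[rec.chrom] = max(lengths[rec.chrom], rec.end + config.gene_spacing)
    return lengths


# ---------------------------------------------------------------------------
# ChIP cohort
# ---------------------------------------------------------------------------

@dataclass
class ChipCohort:
    sheet: SampleSheet
    annotation: list[TRNAGeneRecord]
    truth: SyntheticTruth
    chrom_lengths: dict[str, int]

    def write(self, out_dir: str | Path) -> None:
        """Write genes BED, per-sample fragment BEDs, sheet and truth tables."""
        from .annotation import write_bed6

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed6(self.annotation, out / "genes.bed")
        lines = ["sample_id\tcondition\tchip\tinput"]
        for row in self.sheet:
            chip_name = f"{row.sample_id}_chip.bed"
            input_name = f"{row.sample_id}_input.bed"
            for src, fname in ((row.chip, chip_name), (row.input, input_name)):
                frags = src.fragments()
                with open(out / fname, "w") as fh:
                    for chrom, start, end in frags.itertuples(index=False):
                        fh.write(f"{chrom}\t{start}\t{end}\n")
            lines.append(f"{row.sample_id}\t{row.condition}\t{chip_name}\t{input_name}")
        (out / "sample_sheet.tsv").write_text("\n".join(lines) + "\n")
        self.truth.write(out)


def simulate_chip_cohort(
    config: SyntheticConfig,
    annotation: Sequence[TRNAGeneRecord] | None = None,
) -> ChipCohort:
    """Simulate ChIP and input fragment tracks for a tumour cohort.

    Per sample s and isoacceptor family f the budget is
    ``A_{f,s} = exp(N(mu_f, sigma_budget))`` with mu_f fixed across samples;
    member weights are an independent ``Dirichlet(alpha_sel)`` draw per
    family per sample, and each gene receives ``Poisson(A_{f,s} * w_{g,s})``
    fragments placed uniformly within its ±flank window. Uniform genome-wide
    background is added to the ChIP track, and the input track is pure
    uniform background at its own (higher) rate. Metastatic samples reuse
    the primary parameters, optionally with a per-family multiplicative
    log-normal shift (off by default).
    """
    rng = np.random.default_rng(config.seed)
    annotation = list(annotation) if annotation is not None else make_annotation(config)
    lengths = chromosome_lengths(config, annotation)
    windows = {rec.gene_id: window_of(rec, flank=config.flank,
                                      chrom_length=lengths[rec.chrom])
               for rec in annotation}

    fam_keys: list[str] = []
    fam_members: dict[str, list[str]] = {}
    for rec in annotation:
        key = rec.isoacceptor_key
        if key not in fam_members:
            fam_members[key] = []
            fam_keys.append(key)
        fam_members[key].append(rec.gene_id)
    gene_ids = [rec.gene_id for rec in annotation]

    sample_ids = (
        [f"P_{i + 1:03d}" for i in range(config.n_primary)]
        + [f"M_{i + 1:03d}" for i in range(config.n_metastatic)]
    )
    conditions = (["primary"] * config.n_primary
                  + ["metastatic"] * config.n_metastatic)

    mu_f = pd.Series(
        rng.normal(config.family_budget_log_mean, config.family_budget_log_sd,
                   size=len(fam_keys)),
        index=fam_keys, name="mu_f",
    )
    met_shift = pd.Series(
        rng.normal(0.0, config.met_shift_sd, size=len(fam_keys))
        if config.met_shift_sd > 0 else np.zeros(len(fam_keys)),
        index=fam_keys,
    )

    budgets = pd.DataFrame(index=fam_keys, columns=sample_ids, dtype=float)
    weights = pd.DataFrame(index=gene_ids, columns=sample_ids, dtype=float)
    rates = pd.DataFrame(index=gene_ids, columns=sample_ids, dtype=float)
    rows: list[SampleRow] = []

    for sample_id, condition in zip(sample_ids, conditions):
        chip_chunks: list[pd.DataFrame] = []
        for key in fam_keys:
            members = fam_members[key]
            log_a = rng.normal(mu_f[key], config.sigma_budget)
            if condition == "metastatic":
                log_a += met_shift[key]
            a = math.exp(log_a)
            w = rng.dirichlet(np.full(len(members), config.alpha_sel))
            budgets.loc[key, sample_id] = a
            lam = a * w
            counts = rng.poisson(lam)
            weights.loc[members, sample_id] = w
            rates.loc[members, sample_id] = lam
            for gene, k in zip(members, counts):
                if k == 0:
                    continue
                win = windows[gene]
                mid = rng.integers(win.start, win.end, size=k)
                starts = np.maximum(mid - config.fragment_length // 2, 0)
                chip_chunks.append(pd.DataFrame({
                    "chrom": win.chrom, "start": starts,
                    "end": starts + config.fragment_length,
                }))
        chip_chunks.append(_uniform_background(
            rng, lengths, config.background_per_kb, config.fragment_length))
        input_frame = _uniform_background(
            rng, lengths, config.input_per_kb, config.fragment_length)
        chip_frame = (
            pd.concat(chip_chunks, ignore_index=True)
            .sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )
        rows.append(SampleRow(
            sample_id=sample_id, condition=condition,
            chip=FragmentSource(f"{sample_id}_chip", frame=chip_frame),
            input=FragmentSource(f"{sample_id}_input", frame=input_frame),
        ))

    truth = SyntheticTruth(
        family_log_means=mu_f, budgets=budgets,
        member_weights=weights, expected_rates=rates,
    )
    return ChipCohort(
        sheet=SampleSheet(rows), annotation=annotation,
        truth=truth, chrom_lengths=lengths,
    )


def _uniform_background(
    rng: np.random.Generator,
    lengths: dict[str, int],
    rate_per_kb: float,
    fragment_length: int,
) -> pd.DataFrame:
    chunks = []
    for chrom in sorted(lengths):
        length = lengths[chrom]
        n = rng.poisson(rate_per_kb * length / 1000.0)
        if n == 0:
            continue
        starts = rng.integers(0, max(1, length - fragment_length), size=n)
        chunks.append(pd.DataFrame({
            "chrom": chrom, "start": np.sort(starts),
            "end": np.sort(starts) + fragment_length,
        }))
    if not chunks:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def _censoring_upper_bound(h: np.ndarray, target: float) -> float:
    """Upper bound of the uniform censoring time giving the target fraction.

    P(C < T) for C ~ U(0, c) and T ~ Exp(h) is (1 − e^{−hc})/(hc); bisect on
    its cohort mean, which decreases from 1 (c→0) to 0 (c→∞).
    """

    def frac(c: float) -> float:
        hc = h * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target and hi < 1e9:
        hi *= 2.0
    if frac(hi) > target:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival_cohort(
    config: SyntheticConfig,
    expression: pd.DataFrame | pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[SurvivalTable, SyntheticTruth]:
    """Survival times whose hazard depends on one unit's expression.

    Patient i's hazard is ``h0 * exp(beta_true * z_i)`` with z the
    standardized expression of ``config.effect_unit`` (a Series is used
    directly); event times are exponential, censoring is independent
    uniform calibrated to the target censoring fraction, and follow-up is
    truncated at the horizon if one is set. Times are reported in days.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(expression, pd.Series):
        expr = expression
        unit = expression.name or config.effect_unit or "unit"
    else:
        unit = config.effect_unit
        if unit is None or unit not in expression.index:
            raise ValueError(
                f"effect_unit {unit!r} not present in the expression matrix"
            )
        expr = expression.loc[unit]
    expr = expr.astype(float)
    sd = expr.std(ddof=1)
    z = (expr - expr.mean()) / sd if sd > 0 else expr * 0.0
    h = config.baseline_hazard * np.exp(config.beta_true * z.to_numpy())

    t_event = rng.exponential(1.0 / h)  # years
    if config.censoring_fraction > 0:
        c_max = _censoring_upper_bound(h, config.censoring_fraction)
        t_cens = rng.uniform(0.0, c_max, size=h.size)
        achieved = float(np.mean(t_cens < t_event))
        if abs(achieved - config.censoring_fraction) > 0.1:
            log.warning(
                "simulate_survival_cohort: target censoring %.2f, achieved %.2f",
                config.censoring_fraction, achieved,
            )
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(h.size, dtype=int)
    if config.horizon_years is not None:
        time, event = administrative_censor(time, event, config.horizon_years)
    time_days = np.maximum(np.round(time * 365.25), 1.0)
    frame = pd.DataFrame(
        {"time": time_days, "event": event},
        index=pd.Index(expr.index, name="patient_id"),
    )
    truth = SyntheticTruth(
        beta_true=config.beta_true,
        risk_scores=pd.Series(h, index=expr.index, name="hazard"),
    )
    return SurvivalTable(frame=frame, time_unit="days"), truth
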