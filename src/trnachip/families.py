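"""Hierarchical aggregation of per-gene signal to tRNA family levels.

A family's signal is the sum of its member genes' Q-values (a family-level
"activity budget"), computed at the isodecoder, isoacceptor or isotype
level. With no missing data the per-sample total is conserved across
levels, and aggregation commutes with the hierarchy (gene → isodecoder →
isoacceptor equals gene → isoacceptor directly).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    FamilyLevel,
    GeneNameError,
    TRNAGeneRecord,
    group_by_level,
    parse_gene_name,
)
from .quantify import SignalMatrix

log = logging.getLogger(__name__)

MissingPolicy = Literal["omit", "propagate"]


def _key_at_level(gene_or_key: str, level: FamilyLevel) -> str:
    """Group key at ``level`` for a gene id *or* a finer-level group key."""
    if gene_or_key.startswith("tRNA-"):
        iso, anti, fam, _copy = parse_gene_name(gene_or_key)
        parts = [iso, anti, str(fam)]
    else:
        parts = gene_or_key.split("-")
        valid = (
            1 <= len(parts) <= 3
            and re.fullmatch(r"[A-Za-z]+[0-9]*", parts[0])
            and (len(parts) < 2 or re.fullmatch(r"[ACGTN]{3}", parts[1]))
            and (len(parts) < 3 or parts[2].isdigit())
        )
        if not valid:
            raise GeneNameError(f"cannot parse group key {gene_or_key!r}")
    if level is FamilyLevel.isotype:
        return parts[0]
    if level is FamilyLevel.isoacceptor:
        if len(parts) < 2:
            raise GeneNameError(
                f"key {gene_or_key!r} is coarser than level {level.name}"
            )
        return "-".join(parts[:2])
    if level is FamilyLevel.isodecoder:
        if len(parts) < 3:
            raise GeneNameError(
                f"key {gene_or_key!r} is coarser than level {level.name}"
            )
        return "-".join(parts[:3])
    return gene_or_key  # gene level: identity


@dataclass
class AggregatedMatrix:
    """Family groups × samples sums of member Q-values."""

    values: pd.DataFrame
    level: FamilyLevel
    member_count: pd.Series
    effective_n: pd.DataFrame
    missing_policy: MissingPolicy = "omit"
    statistic: str = "sum"

    @property
    def group_keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "member_count", self.member_count)
        out.insert(0, "level", self.level.name)
        out.to_csv(path, sep="\t", index_label="group_key")


def aggregate(
    matrix: SignalMatrix | AggregatedMatrix | pd.DataFrame,
    level: FamilyLevel | str,
    missing_policy: MissingPolicy = "omit",
    statistic: Literal["sum", "mean"] = "sum",
) -> AggregatedMatrix:
    """Aggregate gene- (or finer-family-) level signal to ``level``.

    ``omit`` (default) sums over the non-missing members and records the
    effective member count per cell; ``propagate`` makes a group cell
    missing as soon as any member is missing. ``sum`` is the standard
    statistic (family totals); ``mean`` is offered for sensitivity analyses
    with unequal family sizes.

    Row keys that cannot be parsed into the hierarchy raise, listing the
    offenders.
    """
    level = FamilyLevel.coerce(level)
    if isinstance(matrix, SignalMatrix):
        frame = matrix.values
    elif isinstance(matrix, AggregatedMatrix):
        if level < matrix.level:
            raise ValueError(
                f"cannot refine a {matrix.level.name}-level matrix to {level.name}"
            )
        frame = matrix.values
    else:
        frame = matrix

    keys: list[str] = []
    bad: list[str] = []
    for row_key in frame.index:
        try:
            keys.append(_key_at_level(str(row_key), level))
        except GeneNameError:
            bad.append(str(row_key))
    if bad:
        raise GeneNameError(
            f"{len(bad)} row id(s) not parseable into the family hierarchy: "
            + ", ".join(bad[:10])
        )

    key_series = pd.Series(keys, index=frame.index)
    grouped = frame.groupby(key_series, sort=False)
    if statistic == "sum":
        values = grouped.sum(min_count=1)  # all-NaN group stays NaN
    elif statistic == "mean":
        values = grouped.mean()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    effective_n = frame.notna().groupby(key_series, sort=False).sum()
    member_count = key_series.groupby(key_series, sort=False).size()
    if isinstance(matrix, AggregatedMatrix):
        # member counts in genes, accumulated through the hierarchy
        member_count = matrix.member_count.groupby(key_series, sort=False).sum()
    if missing_policy == "propagate":
        incomplete = effective_n.lt(member_count, axis=0)
        values = values.mask(incomplete)
    elif missing_policy != "omit":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return AggregatedMatrix(
        values=values,
        level=level,
        member_count=member_count,
        effective_n=effective_n,
        missing_policy=missing_policy,
        statistic=statistic,
    )


def family_sizes(
    records: Sequence[TRNAGeneRecord], level: FamilyLevel | str
) -> dict[str, int]:
    """Member-gene count per family group at ``level``."""
    return {k: len(v) for k, v in group_by_level(records, level).items()}


def proportional_distribution(
    agg: AggregatedMatrix | pd.DataFrame,
    sample_group: Iterable[str] | None = None,
) -> pd.Series:
    """Per-group share of total signal, averaged over a set of samples.

    Each column is first normalized to sum to 1 over its non-missing groups
    (so shares are comparable across samples of different overall signal),
    then shares are averaged across the selected samples. Columns with no
    usable signal are excluded with a warning.
    """
    frame = agg.values if isinstance(agg, AggregatedMatrix) else agg
    if sample_group is not None:
        frame = frame[list(sample_group)]
    totals = frame.sum(skipna=True)
    dead = totals[(totals == 0) | frame.isna().all()].index
    if len(dead):
        log.warning(
            "proportional_distribution: excluding sample(s) with no signal: %s",
            ", ".join(map(str, dead)),
        )
        frame = frame.drop(columns=dead)
        totals = totals.drop(dead)
    if frame.shape[1] == 0:
        raise ValueError("no samples with usable signal")
    shares = frame.div(totals, axis=1)
    return shares.mean(axis=1, skipna=True)
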