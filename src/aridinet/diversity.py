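"""Rarefaction, alpha diversity, group statistics and OTU set summaries.

Alpha diversity is computed on rarefied counts (subsampled without
replacement to a common depth) so that richness comparisons are not driven
by unequal sequencing effort.  Shannon entropy defaults to base 2 (bits),
the convention of common amplicon tooling; Simpson is reported as the
Gini-Simpson index 1 - sum(p^2).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("aridinet")


@dataclass
class GroupTestResult:
    """Outcome of a between-group test on a per-sample metric.

    For one-way ANOVA, ``statistic`` is the F value and ``p_value`` its
    p; for Tukey HSD, the per-pair studentized-range results live in
    ``pairwise`` (columns group1, group2, meandiff, p_adj) and the scalar
    fields are NaN.
    """

    statistic: float
    p_value: float
    groups: tuple
    pairwise: pd.DataFrame | None = None
    excluded_groups: tuple = ()


@dataclass
class VennPartition:
    """Zone-membership partition of the OTUs observed in a compartment."""

    zones: tuple
    per_zone: dict
    core: set
    zone_specific: dict
    patterns: dict = field(repr=False)

    @property
    def universe(self) -> set:
        return set(self.patterns)


# ---------------------------------------------------------------------------


def rarefy(counts: pd.DataFrame, depth: int = 1000, seed=None) -> pd.DataFrame:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged).  Sampling
    is multivariate hypergeometric, so a sample whose total equals ``depth``
    is returned unchanged.  Reproducible given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [s for s in counts.columns if s not in set(keep)]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    out = {}
    for sample in keep:
        col = counts[sample].to_numpy(dtype=np.int64)
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index)


def alpha_diversity(
    counts: pd.DataFrame, shannon_base: float = 2.0, simpson_kind: str = "gini"
) -> pd.DataFrame:
    """Per-sample Shannon, Simpson and observed-OTU richness.

    Parameters
    ----------
    counts
        (Rarefied) count table, OTUs x samples.
    shannon_base
        Logarithm base for Shannon entropy (2 -> bits, e -> nats).
    simpson_kind
        ``"gini"`` for 1 - sum(p^2) (default) or ``"dominance"`` for
        sum(p^2).
    """
    if simpson_kind not in ("gini", "dominance"):
        raise ValueError(f"unknown simpson_kind: {simpson_kind!r}")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    p = counts / totals
    shannon = p.apply(lambda col: stats.entropy(col, base=shannon_base), axis=0)
    d = (p**2).sum(axis=0)
    simpson = d if simpson_kind == "dominance" else 1.0 - d
    observed = (counts > 0).sum(axis=0)
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "observed_otus": observed.astype(int)}
    )


def anova_oneway(values, groups) -> GroupTestResult:
    """Classical one-way ANOVA on a per-sample metric.

    Degenerate input (all values identical) yields F = 0, p = 1 rather
    than the NaN scipy would produce.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    chunks = [values[groups == g] for g in labels]
    if any(len(c) < 1 for c in chunks):
        raise ValueError("every group needs >=1 value")
    if len(values) - len(labels) < 1:
        raise ValueError("need at least one group with >=2 values")
    if np.ptp(values) == 0:
        return GroupTestResult(0.0, 1.0, tuple(labels))
    f, p = stats.f_oneway(*chunks)
    return GroupTestResult(float(f), float(p), tuple(labels))


def tukey_hsd(values, groups) -> GroupTestResult:
    """Tukey HSD pairwise comparisons (Tukey-Kramer under unequal n).

    Groups with fewer than two values are excluded with a warning (a
    single-site zone cannot contribute a within-group variance).  With all
    values identical every adjusted p is 1.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    eligible = sizes[sizes >= 2].index
    excluded = tuple(sizes[sizes < 2].index)
    if excluded:
        warnings.warn(f"tukey_hsd: excluding size-1 groups {list(excluded)}")
    if len(eligible) < 2:
        raise ValueError("need >=2 groups with >=2 values each")
    mask = np.isin(groups, eligible)
    vals, grps = values[mask], groups[mask]
    label_order = sorted(map(str, pd.unique(grps)))
    if np.ptp(vals) == 0:
        pairs = list(itertools.combinations(label_order, 2))
        pairwise = pd.DataFrame(
            {"group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
             "meandiff": 0.0, "p_adj": 1.0}
        )
    else:
        res = pairwise_tukeyhsd(vals, grps.astype(str))
        pairs = list(itertools.combinations(res.groupsunique, 2))
        pairwise = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "meandiff": res.meandiffs,
                "p_adj": res.pvalues,
            }
        )
    return GroupTestResult(
        float("nan"), float("nan"), tuple(label_order), pairwise=pairwise,
        excluded_groups=excluded,
    )


def dominant_otus(table: pd.DataFrame, samples=None, threshold: float = 0.01) -> set:
    """OTUs whose pooled proportion over ``samples`` strictly exceeds
    ``threshold`` (default 1%).

    Pooling is total abundance of the OTU over the subset divided by the
    subset's grand total, so the strict ``> 1%`` convention for "dominant"
    taxa excludes an OTU sitting exactly at the threshold.
    """
    sub = table if samples is None else table[list(samples)]
    if sub.shape[1] == 0:
        raise ValueError("empty sample subset")
    pooled = sub.sum(axis=1) / sub.to_numpy().sum()
    return set(pooled.index[pooled > threshold])


def venn_partition(counts: pd.DataFrame, metadata: pd.DataFrame, compartment: str) -> VennPartition:
    """Partition a compartment's observed OTUs by zone-membership pattern.

    An OTU is present in a zone when it has a positive count in at least
    one sample of that zone (pre-rarefaction, post organelle filter).  The
    core set is the intersection across all zones present; zone-specific
    sets contain OTUs seen in exactly one zone.
    """
    meta = metadata[metadata["compartment"] == compartment]
    zones = [z for z in ("humid", "semi_arid", "upper_arid", "lower_arid") if z in set(meta["zone"])]
    if len(zones) < 2:
        raise ValueError(f"need >=2 zones in compartment {compartment!r}")
    per_zone = {}
    for zone in zones:
        samples = meta.index[meta["zone"] == zone]
        present = counts[samples].sum(axis=1) > 0
        per_zone[zone] = set(counts.index[present])
    patterns = {}
    for otu in set().union(*per_zone.values()):
        patterns[otu] = frozenset(z for z in zones if otu in per_zone[z])
    core = set.intersection(*(per_zone[z] for z in zones))
    zone_specific = {
        z: {otu for otu, pat in patterns.items() if pat == frozenset({z})} for z in zones
    }
    return VennPartition(tuple(zones), per_zone, core, zone_specific, patterns)
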