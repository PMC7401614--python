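"""Classification of OTUs as increased / decreased / neutral along the
aridity gradient.

The rule is correlational, not a hypothesis test: an OTU whose abundance
correlates with the ordered zone rank (humid=0 ... lower_arid=3) beyond a
strict threshold (r > 0.9 increased, r < -0.9 decreased) is called a
gradient responder.  OTUs below a pooled-abundance eligibility cutoff
(0.1% by default) are excluded before classification.

Two profile modes are offered:

``"samples"`` (default)
    r is computed across all samples of the compartment, each carrying its
    zone rank.  With tens of samples the null distribution of r is tight,
    so the strict threshold has a negligible false-positive rate.
``"zone_means"``
    r is computed on the four zone-mean abundances against rank 0..3.
    This mirrors zone-level summaries, but note that with only four points
    the null distribution of Pearson r is exactly uniform on [-1, 1], so a
    |r| > 0.9 cutoff passes ~10% of pure-noise profiles; use it for
    inspection, not for error-controlled screening.

Zone-mean ratio profiles against the humid zone are reported alongside r
so a humid-referenced reading of the rule is auditable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ZONES

TREND_LABELS = ("increased", "decreased", "neutral", "excluded_low_abundance")


def _rowwise_pearson(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of each row of Y against x; 0 where either side is constant."""
    xc = x - x.mean()
    yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum(axis=1))
    denom = sy * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    r[denom == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _rowwise_spearman(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    ry = stats.rankdata(Y, axis=1)
    rx = stats.rankdata(x)
    return _rowwise_pearson(ry, rx)


def zone_profile(rel: pd.DataFrame, metadata: pd.DataFrame, compartment: str, otu=None):
    """Zone-mean abundance profile(s) for a compartment, ordered by rank.

    Returns a DataFrame (OTUs x 4 zones), or a single 4-vector Series when
    ``otu`` is given.  Every zone must be represented in the compartment.
    """
    meta = metadata[metadata["compartment"] == compartment]
    missing = [z for z in ZONES if z not in set(meta["zone"])]
    if missing:
        raise ValueError(f"zones absent from compartment {compartment!r}: {missing}")
    cols = {z: rel[meta.index[meta["zone"] == z]].mean(axis=1) for z in ZONES}
    profiles = pd.DataFrame(cols)[list(ZONES)]
    if otu is not None:
        return profiles.loc[otu]
    return profiles


class GradientTrendClassifier(BaseEstimator):
    """Label OTUs by their monotone trend along the aridity gradient.

    Parameters
    ----------
    r_threshold : float, default 0.9
        Strict cutoff: increased iff r > r_threshold, decreased iff
        r < -r_threshold.
    min_pooled_abundance : float, default 0.001
        Eligibility: OTUs with pooled (mean) relative abundance at or
        below this fraction are labeled ``excluded_low_abundance``.
    method : {"pearson", "spearman"}
    profile_mode : {"samples", "zone_means"}
        See module docstring.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : DataFrame indexed by OTU id with columns ``compartment``,
        ``label``, ``r``, ``pooled_abundance``, the four zone means
        (``mean_<zone>``) and the four humid-referenced ratios
        (``ratio_<zone>``).
    labels_ : Series of labels.
    """

    def __init__(self, r_threshold: float = 0.9, min_pooled_abundance: float = 0.001,
                 method: str = "pearson", profile_mode: str = "samples"):
        self.r_threshold = r_threshold
        self.min_pooled_abundance = min_pooled_abundance
        self.method = method
        self.profile_mode = profile_mode

    def fit(self, X: pd.DataFrame, metadata: pd.DataFrame, compartment: str | None = None):
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.profile_mode not in ("samples", "zone_means"):
            raise ValueError(f"unknown profile_mode: {self.profile_mode!r}")
        if compartment is None:
            comps = pd.unique(metadata.loc[metadata.index.intersection(X.columns), "compartment"])
            if len(comps) != 1:
                raise ValueError("compartment must be given when metadata mixes compartments")
            compartment = comps[0]
        meta = metadata[metadata["compartment"] == compartment]
        samples = [s for s in X.columns if s in set(meta.index)]
        rel = X[samples]

        profiles = zone_profile(rel, metadata, compartment)
        rowfun = _rowwise_pearson if self.method == "pearson" else _rowwise_spearman
        if self.profile_mode == "zone_means":
            r = rowfun(profiles.to_numpy(), np.arange(len(ZONES), dtype=float))
        else:
            ranks = meta.loc[samples, "zone_rank"].to_numpy(dtype=float)
            r = rowfun(rel.to_numpy(), ranks)

        pooled = rel.mean(axis=1).to_numpy()
        labels = np.where(
            pooled <= self.min_pooled_abundance,
            "excluded_low_abundance",
            np.where(r > self.r_threshold, "increased",
                     np.where(r < -self.r_threshold, "decreased", "neutral")),
        )

        humid = profiles["humid"].to_numpy().copy()
        nonzero = rel.to_numpy()[rel.to_numpy() > 0]
        eps = nonzero.min() / 2.0 if nonzero.size else 1.0
        humid[humid == 0] = eps
        ratios = profiles.to_numpy() / humid[:, None]

        res = pd.DataFrame(index=rel.index)
        res["compartment"] = compartment
        res["label"] = labels
        res["r"] = r
        res["pooled_abundance"] = pooled
        for j, z in enumerate(ZONES):
            res[f"mean_{z}"] = profiles[z].to_numpy()
        for j, z in enumerate(ZONES):
            res[f"ratio_{z}"] = ratios[:, j]
        self.results_ = res
        self.labels_ = res["label"]
        self.compartment_ = compartment
        return self

    def fit_predict(self, X, metadata, compartment=None):
        return self.fit(X, metadata, compartment).labels_


def classify_trend(
    rel: pd.DataFrame, metadata: pd.DataFrame, compartment: str,
    r_threshold: float = 0.9, min_pooled_abundance: float = 0.001,
    method: str = "pearson", profile_mode: str = "samples",
) -> pd.DataFrame:
    """Functional wrapper around :class:`GradientTrendClassifier`."""
    clf = GradientTrendClassifier(
        r_threshold=r_threshold, min_pooled_abundance=min_pooled_abundance,
        method=method, profile_mode=profile_mode,
    )
    return clf.fit(rel, metadata, compartment).results_


def shared_trend_otus(rhizo: pd.DataFrame, endo: pd.DataFrame, label: str = "increased") -> set:
    """OTUs carrying the same trend label in both compartments."""
    if label not in TREND_LABELS:
        raise ValueError(f"unknown label: {label!r}")
    a = set(rhizo.index[rhizo["label"] == label])
    b = set(endo.index[endo["label"] == label])
    return a & b
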