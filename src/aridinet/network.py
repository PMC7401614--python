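"""Signed, FDR-controlled co-occurrence network over trend-classified OTUs
and soil parameters.

Features live on a shared site axis: each gradient-responding OTU (per
compartment) contributes its site-mean relative abundance, and each soil
parameter contributes its per-site value.  All unordered feature pairs are
correlated (Pearson and Spearman); p-values are Benjamini-Hochberg
adjusted within each method's family; an edge is kept when at least one
method reaches |r| >= r_min with an adjusted (or raw) p at most alpha.
Edge sign encodes co-presence (+) versus mutual exclusion (-).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import RANKS

logger = logging.getLogger("aridinet")

FEATURE_CLASSES = (
    "rhizo_increased", "rhizo_decreased",
    "endo_increased", "endo_decreased",
    "soil_parameter",
)
_COMP_SHORT = {"rhizosphere": "rhizo", "endosphere": "endo"}


@dataclass
class FeatureVectorSet:
    """Site-aligned feature matrix with per-feature class annotations."""

    values: pd.DataFrame  # sites x features
    classes: pd.Series  # feature -> class
    taxonomy: dict = field(default_factory=dict)  # feature -> lineage string


@dataclass
class SubnetworkSplit:
    """Edge partition of a co-occurrence network by trend class.

    ``increased`` / ``decreased`` are subgraphs holding each class's OTU
    nodes, the soil parameters attached to them, and the edges touching
    that class only; ``between_edges`` are increased-decreased edges and
    ``soil_soil_edges`` connect two environmental parameters.  Every edge
    of the full network lands in exactly one of the four blocks.
    """

    increased: nx.Graph
    decreased: nx.Graph
    between_edges: list
    soil_soil_edges: list


def _trend_of(cls: str):
    if cls.endswith("_increased"):
        return "increased"
    if cls.endswith("_decreased"):
        return "decreased"
    return None


def build_feature_vectors(
    rel: pd.DataFrame,
    metadata: pd.DataFrame,
    trends: dict,
    soil: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> FeatureVectorSet:
    """Assemble the site-aligned feature matrix for network inference.

    Parameters
    ----------
    trends
        Mapping compartment -> trend results DataFrame (from
        :func:`aridinet.trend.classify_trend`); only OTUs labeled
        increased/decreased become features.
    soil
        Per-site soil parameter table.

    Feature names are ``"<compartment>:<otu_id>"`` for OTUs and the bare
    parameter name for soil variables.  Sites are the intersection of
    those with samples (any compartment used) and soil coverage; fewer
    than 3 shared sites is an error since correlations would be trivial.
    """
    columns, classes, taxo = {}, {}, {}
    for compartment, res in trends.items():
        short = _COMP_SHORT[compartment]
        meta = metadata[metadata["compartment"] == compartment]
        responders = res.index[res["label"].isin(("increased", "decreased"))]
        site_means = {}
        for site in pd.unique(meta["site_id"]):
            samples = [s for s in meta.index[meta["site_id"] == site] if s in rel.columns]
            if samples:
                site_means[site] = rel.loc[responders, samples].mean(axis=1)
        site_df = pd.DataFrame(site_means).T  # sites x responders
        for otu in responders:
            name = f"{short}:{otu}"
            columns[name] = site_df[otu]
            classes[name] = f"{short}_{res.loc[otu, 'label']}"
            if taxonomy is not None and otu in taxonomy.index:
                lineage = taxonomy.loc[otu, list(RANKS)].dropna()
                taxo[name] = ";".join(map(str, lineage))
    for param in soil.columns:
        columns[param] = soil[param]
        classes[param] = "soil_parameter"
    values = pd.DataFrame(columns).dropna(axis=0)
    if values.shape[0] < 3:
        raise ValueError(f"only {values.shape[0]} aligned sites; need >= 3")
    return FeatureVectorSet(values, pd.Series(classes), taxo)


def correlate_pairs(values: pd.DataFrame, methods=("pearson", "spearman")) -> pd.DataFrame:
    """Correlate all unordered feature pairs with each method.

    Returns a tidy DataFrame (source, target, method, r, p).  Features
    with zero variance are skipped (their correlations are undefined) and
    logged.
    """
    X = values.to_numpy(dtype=float)
    names = list(values.columns)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 aligned observations")
    variable = X.std(axis=0) > 0
    skipped = [n for n, v in zip(names, variable) if not v]
    if skipped:
        logger.info("correlate_pairs: skipping zero-variance features %s", skipped)
    rows = []
    idx = [i for i, v in enumerate(variable) if v]
    for i, j in itertools.combinations(idx, 2):
        for method in methods:
            if method == "pearson":
                r, p = stats.pearsonr(X[:, i], X[:, j])
            elif method == "spearman":
                r, p = stats.spearmanr(X[:, i], X[:, j])
            else:
                raise ValueError(f"unknown method: {method!r}")
            rows.append((names[i], names[j], method, float(r), float(p)))
    return pd.DataFrame(rows, columns=["source", "target", "method", "r", "p"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


class CooccurrenceNetwork(BaseEstimator):
    """Threshold correlations into a signed co-occurrence graph.

    Parameters
    ----------
    r_min : float, default 0.9
        Inclusive magnitude threshold: an edge needs |r| >= r_min.
    alpha : float, default 0.05
        Significance cutoff applied to BH-adjusted p-values
        (``p_mode="bh"``) or raw p-values (``p_mode="raw"``).
    methods : tuple of {"pearson", "spearman"}
    combine : {"or", "and"}
        Whether one qualifying method suffices for an edge (default) or
        all must qualify.  The qualifying method with the larger |r|
        annotates the edge either way.

    Attributes (after :meth:`fit`)
    ------------------------------
    correlations_ : tidy per-pair/per-method DataFrame with q-values.
    edges_ : DataFrame (source, target, method, r, p, q, sign).
    graph_ : networkx.Graph with node attributes ``feature_class`` and
        ``taxonomy`` and edge attributes r, p, q, sign, method.
    """

    def __init__(self, r_min: float = 0.9, alpha: float = 0.05, p_mode: str = "bh",
                 methods=("pearson", "spearman"), combine: str = "or"):
        self.r_min = r_min
        self.alpha = alpha
        self.p_mode = p_mode
        self.methods = methods
        self.combine = combine

    def fit(self, X, y=None):
        if self.p_mode not in ("bh", "raw"):
            raise ValueError(f"unknown p_mode: {self.p_mode!r}")
        if self.combine not in ("or", "and"):
            raise ValueError(f"unknown combine rule: {self.combine!r}")
        if isinstance(X, FeatureVectorSet):
            values, classes, taxonomy = X.values, X.classes, X.taxonomy
        else:
            values = X
            classes = pd.Series("feature", index=values.columns)
            taxonomy = {}
        corr = correlate_pairs(values, methods=self.methods)
        corr["q"] = np.nan
        for method in self.methods:
            mask = corr["method"] == method
            corr.loc[mask, "q"] = bh_fdr(corr.loc[mask, "p"].to_numpy())
        crit = corr["q"] if self.p_mode == "bh" else corr["p"]
        corr["passes"] = (corr["r"].abs() >= self.r_min) & (crit <= self.alpha)
        self.correlations_ = corr

        edges = []
        for (src, tgt), grp in corr.groupby(["source", "target"], sort=False):
            if self.combine == "or":
                ok = grp[grp["passes"]]
            else:
                ok = grp[grp["passes"]] if grp["passes"].all() else grp.iloc[0:0]
            if len(ok) == 0:
                continue
            best = ok.loc[ok["r"].abs().idxmax()]
            edges.append(
                (src, tgt, best["method"], best["r"], best["p"], best["q"],
                 "+" if best["r"] > 0 else "-")
            )
        self.edges_ = pd.DataFrame(
            edges, columns=["source", "target", "method", "r", "p", "q", "sign"]
        )

        g = nx.Graph()
        for name in values.columns:
            g.add_node(name, feature_class=str(classes.get(name, "feature")),
                       taxonomy=str(taxonomy.get(name, "")))
        for row in self.edges_.itertuples(index=False):
            g.add_edge(row.source, row.target, r=float(row.r), p=float(row.p),
                       q=float(row.q), sign=row.sign, method=row.method)
        self.graph_ = g
        return self


def build_network(features, r_min: float = 0.9, alpha: float = 0.05,
                  p_mode: str = "bh", methods=("pearson", "spearman"),
                  combine: str = "or") -> CooccurrenceNetwork:
    """Functional wrapper around :class:`CooccurrenceNetwork`."""
    return CooccurrenceNetwork(
        r_min=r_min, alpha=alpha, p_mode=p_mode, methods=methods, combine=combine
    ).fit(features)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def split_subnetworks(g: nx.Graph) -> SubnetworkSplit:
    """Split the network into increased / decreased subnetworks.

    Each subnetwork holds that trend class's OTU nodes plus the soil
    parameters with at least one edge to the class; its edges are those of
    the full network touching the class's OTUs and no OTU of the other
    class.  Increased-decreased edges and soil-soil edges are returned as
    separate lists, so the four blocks partition the full edge set.
    """
    trend = {n: _trend_of(d.get("feature_class", "")) for n, d in g.nodes(data=True)}
    blocks = {"increased": [], "decreased": [], "between": [], "soil": []}
    for u, v, data in g.edges(data=True):
        tu, tv = trend[u], trend[v]
        if tu is None and tv is None:
            blocks["soil"].append((u, v, data))
        elif {tu, tv} == {"increased", "decreased"}:
            blocks["between"].append((u, v, data))
        else:
            blocks[tu or tv].append((u, v, data))

    subgraphs = {}
    for cls in ("increased", "decreased"):
        sub = nx.Graph()
        for n, d in g.nodes(data=True):
            if trend[n] == cls:
                sub.add_node(n, **d)
        for u, v, data in blocks[cls]:
            for n in (u, v):
                if n not in sub:
                    sub.add_node(n, **g.nodes[n])
            sub.add_edge(u, v, **data)
        subgraphs[cls] = sub
    return SubnetworkSplit(
        subgraphs["increased"], subgraphs["decreased"],
        [(u, v) for u, v, _ in blocks["between"]],
        [(u, v) for u, v, _ in blocks["soil"]],
    )


def rank_hubs(g: nx.Graph, min_degree: int = 56, top_k: int = 22) -> pd.DataFrame:
    """Rank nodes by degree in the full network.

    Keeps nodes with degree >= ``min_degree``, truncated to the ``top_k``
    best; ties broken by node id.  High-degree nodes ("hubs") are the
    candidate keystone taxa of the community.
    """
    rows = [
        (n, g.degree(n), d.get("feature_class", ""), d.get("taxonomy", ""))
        for n, d in g.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "degree", "feature_class", "taxonomy"])
    df = df[df["degree"] >= min_degree]
    df = df.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort")
    return df.head(top_k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(g: nx.Graph, path) -> None:
    """Cytoscape SIF edge list: ``source <tab> pos|neg <tab> target``.

    Isolated nodes are emitted as bare single-column lines, per the SIF
    convention.
    """
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            interaction = "pos" if data.get("sign") == "+" else "neg"
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def write_node_attributes(g: nx.Graph, path) -> None:
    rows = [
        {"node": n, "feature_class": d.get("feature_class", ""),
         "taxonomy": d.get("taxonomy", ""), "degree": g.degree(n)}
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_graph(g: nx.Graph, out_dir, formats=("graphml", "sif"),
                 node_attributes: bool = True, stem: str = "network") -> list:
    """Write the network for external tools; returns written paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "graphml" in formats:
        p = out_dir / f"{stem}.graphml"
        write_graphml(g, p)
        written.append(p)
    if "sif" in formats:
        p = out_dir / f"{stem}.sif"
        write_sif(g, p)
        written.append(p)
    if node_attributes:
        p = out_dir / f"{stem}_nodes.tsv"
        write_node_attributes(g, p)
        written.append(p)
    return written
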