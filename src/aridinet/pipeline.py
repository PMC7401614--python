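"""End-to-end orchestration: filter -> relative abundance -> aggregate ->
rarefy -> alpha -> ordination -> Venn -> dominant -> trend -> network ->
hubs -> exports, with a manifest for reproducibility audits.

All stage handoffs are plain TSV under a run directory with fixed names;
``manifest.json`` echoes the configuration, the seeds and a SHA-256 digest
of every output, so two runs with the same inputs and seeds can be
compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diversity as _div
from . import io as _io
from . import network as _net
from . import ordination as _ord
from . import trend as _trend

logger = logging.getLogger("aridinet")


class PipelineError(RuntimeError):
    """A named, stage-attributed pipeline failure."""


@dataclass
class PipelineConfig:
    otu_path: str
    metadata_path: str
    taxonomy_path: str
    soil_path: str
    out_dir: str
    otu_format: str = "tsv"
    rarefaction_depth: int = 1000
    dominance_threshold: float = 0.01
    trend_r_threshold: float = 0.9
    trend_min_abundance: float = 0.001
    trend_method: str = "pearson"
    trend_profile_mode: str = "samples"
    network_r_min: float = 0.9
    network_alpha: float = 0.05
    network_p_mode: str = "bh"
    hub_min_degree: int = 56
    hub_top_k: int = 22
    n_permutations: int = 5000
    nmds_restarts: int = 20
    shannon_base: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.rarefaction_depth < 1:
            raise PipelineError("config: rarefaction_depth must be >= 1")
        for name in ("dominance_threshold", "trend_min_abundance", "network_alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise PipelineError(f"config: {name} must lie in [0, 1]")
        for name in ("trend_r_threshold", "network_r_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise PipelineError(f"config: {name} must lie in [0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list = []

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised, named
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            stages.append(name)
            logger.info("pipeline stage %s done", name)
            return result

        return deco

    for label, path in (
        ("otu table", cfg.otu_path), ("metadata", cfg.metadata_path),
        ("taxonomy", cfg.taxonomy_path), ("soil table", cfg.soil_path),
    ):
        if not Path(path).exists():
            raise PipelineError(f"missing input: {label} at {path}")

    @stage("read")
    def _read():
        counts = _io.read_otu_table(cfg.otu_path, format=cfg.otu_format)
        metadata = _io.read_sample_metadata(cfg.metadata_path)
        taxonomy = _io.read_taxonomy(cfg.taxonomy_path)
        soil = _io.read_soil(cfg.soil_path)
        unknown = [s for s in counts.columns if s not in metadata.index]
        if unknown:
            raise PipelineError(f"samples without metadata: {unknown[:5]}")
        return counts, metadata.loc[list(counts.columns)], taxonomy, soil

    counts, metadata, taxonomy, soil = _read

    @stage("filter_organelles")
    def filtered():
        return _io.filter_organelle_otus(counts, taxonomy)

    @stage("relative_abundance")
    def rel():
        return _io.relative_abundance(filtered)

    @stage("aggregate_taxa")
    def phylum_table():
        agg = _io.aggregate_taxa(rel, taxonomy, level="phylum", split_proteobacteria=True)
        agg.to_csv(out / "phylum_abundance.tsv", sep="\t")
        return agg

    @stage("rarefy_alpha")
    def alpha():
        rare = _div.rarefy(filtered, depth=cfg.rarefaction_depth, seed=cfg.seed)
        a = _div.alpha_diversity(rare, shannon_base=cfg.shannon_base)
        a.index.name = "sample_id"
        a.to_csv(out / "alpha.tsv", sep="\t")
        return a

    @stage("group_tests")
    def _group_tests():
        rows = []
        for comp in _io.COMPARTMENTS:
            samples = [s for s in alpha.index if metadata.loc[s, "compartment"] == comp]
            if not samples:
                continue
            vals = alpha.loc[samples, "shannon"].to_numpy()
            zones = metadata.loc[samples, "zone"].to_numpy()
            if len(pd.unique(zones)) < 2:
                continue
            res = _div.anova_oneway(vals, zones)
            rows.append({"compartment": comp, "test": "anova_shannon_by_zone",
                         "group1": "", "group2": "", "statistic": res.statistic,
                         "p": res.p_value})
            try:
                tk = _div.tukey_hsd(vals, zones)
            except ValueError:
                continue
            for t in tk.pairwise.itertuples(index=False):
                rows.append({"compartment": comp, "test": "tukey_shannon_by_zone",
                             "group1": t.group1, "group2": t.group2,
                             "statistic": t.meandiff, "p": t.p_adj})
        df = pd.DataFrame(rows)
        df.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        return df

    @stage("ordination")
    def _ordination():
        d = _ord.bray_curtis(rel)
        d.to_csv(out / "bray_curtis.tsv", sep="\t")
        emb = _ord.NonmetricMDS(n_restarts=cfg.nmds_restarts, random_state=cfg.seed).fit(d)
        coords = emb.embedding_.copy()
        coords.index.name = "sample_id"
        with open(out / "nmds.tsv", "w") as fh:
            fh.write(f"# stress\t{emb.stress_:.6f}\n")
            coords.to_csv(fh, sep="\t")
        perm_rows = []
        res = _ord.permanova(d, metadata["compartment"],
                             permutations=cfg.n_permutations, seed=cfg.seed)
        perm_rows.append({"factor": "compartment", "subset": "all",
                          "pseudo_F": res.pseudo_f, "p": res.p_value,
                          "n_permutations": res.n_permutations})
        for comp in _io.COMPARTMENTS:
            samples = [s for s in d.index if metadata.loc[s, "compartment"] == comp]
            zones = metadata.loc[samples, "zone"]
            if len(samples) and zones.value_counts().ge(2).all() and zones.nunique() >= 2:
                res = _ord.permanova(d.loc[samples, samples], zones,
                                     permutations=cfg.n_permutations, seed=cfg.seed)
                perm_rows.append({"factor": "zone", "subset": comp,
                                  "pseudo_F": res.pseudo_f, "p": res.p_value,
                                  "n_permutations": res.n_permutations})
        pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
        return emb.stress_

    @stage("venn")
    def _venn():
        rows = []
        for comp in _io.COMPARTMENTS:
            try:
                part = _div.venn_partition(filtered, metadata, comp)
            except ValueError:
                continue
            for otu, pat in sorted(part.patterns.items()):
                bits = "".join("1" if z in pat else "0" for z in part.zones)
                category = ("core" if otu in part.core
                            else f"specific:{next(iter(pat))}" if len(pat) == 1 else "shared")
                rows.append({"otu_id": otu, "compartment": comp,
                             "pattern": bits, "category": category})
        pd.DataFrame(rows).to_csv(out / "venn.tsv", sep="\t", index=False)

    @stage("dominant")
    def _dominant():
        rows = []
        for comp in _io.COMPARTMENTS:
            samples = [s for s in filtered.columns if metadata.loc[s, "compartment"] == comp]
            if not samples:
                continue
            for otu in sorted(_div.dominant_otus(filtered, samples, cfg.dominance_threshold)):
                rows.append({"otu_id": otu, "compartment": comp})
        pd.DataFrame(rows).to_csv(out / "dominant_otus.tsv", sep="\t", index=False)

    @stage("trend")
    def trends():
        results = {}
        for comp in _io.COMPARTMENTS:
            if comp not in set(metadata["compartment"]):
                continue
            results[comp] = _trend.classify_trend(
                rel, metadata, comp,
                r_threshold=cfg.trend_r_threshold,
                min_pooled_abundance=cfg.trend_min_abundance,
                method=cfg.trend_method, profile_mode=cfg.trend_profile_mode,
            )
        combined = pd.concat(results.values())
        combined.index.name = "otu_id"
        combined.to_csv(out / "trends.tsv", sep="\t")
        return results

    @stage("network")
    def net():
        features = _net.build_feature_vectors(rel, metadata, trends, soil, taxonomy)
        model = _net.CooccurrenceNetwork(
            r_min=cfg.network_r_min, alpha=cfg.network_alpha, p_mode=cfg.network_p_mode,
        ).fit(features)
        model.edges_.to_csv(out / "edges.tsv", sep="\t", index=False)
        _net.write_graphml(model.graph_, out / "network.graphml")
        _net.write_sif(model.graph_, out / "network.sif")
        _net.write_node_attributes(model.graph_, out / "node_attributes.tsv")
        hubs = _net.rank_hubs(model.graph_, cfg.hub_min_degree, cfg.hub_top_k)
        hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
        return model

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "stages": stages,
        "nmds_stress": _ordination,
        "n_samples": int(counts.shape[1]),
        "n_otus_input": int(counts.shape[0]),
        "n_otus_after_filter": int(filtered.shape[0]),
        "n_edges": int(net.edges_.shape[0]),
        "files": {},
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
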