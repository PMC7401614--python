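"""Gradient-structured synthetic microbiome datasets with known truth.

The generator emulates the study design this package analyzes: four
bioclimatic zones ordered by increasing aridity, several sites per zone,
rhizosphere and endosphere samples per site, compositional sequencing
counts, and per-site soil physicochemical covariates trending with the
zone order.  Planted "increased" OTUs have their base abundance multiplied
by ``fold_change_per_zone ** zone_rank`` before renormalization (planted
"decreased" OTUs mirror this), so their expected zone profiles are
strictly monotone; all other OTUs are neutral.  Counts are
Dirichlet-multinomial, giving overdispersion beyond the multinomial.

A reference soil survey of 19 Tunisian *Opuntia ficus-indica* plantation
sites (one humid, six semi-arid, nine upper-arid, three lower-arid) ships
as a fixture for realistic soil inputs; see :func:`load_table2_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .io import SOIL_COLUMNS, ZONES

_ZONE_CODE = {"humid": "H", "semi_arid": "S", "upper_arid": "U", "lower_arid": "L"}

#: Phylum pool (weights) used to annotate synthetic OTUs; mirrors the major
#: phyla of arid-soil prokaryotic communities.
_PHYLA = (
    ("Actinobacteria", 0.25), ("Proteobacteria", 0.25), ("Firmicutes", 0.15),
    ("Chloroflexi", 0.08), ("Acidobacteria", 0.07), ("Bacteroidetes", 0.07),
    ("Cyanobacteria", 0.05), ("Gemmatimonadetes", 0.03),
    ("Verrucomicrobia", 0.03), ("Euryarchaeota", 0.02),
)
_PROTEO_CLASSES = (
    ("Alphaproteobacteria", 0.4), ("Betaproteobacteria", 0.3),
    ("Gammaproteobacteria", 0.2), ("Deltaproteobacteria", 0.1),
)

#: Per-parameter (mean, sd, gradient sign): -1 falls with aridity, +1 rises,
#: 0 flat.  Magnitudes echo the reference soil survey; signs follow the
#: reported directions (humidity, TP, TOC, Fe, K and CEC decline along the
#: gradient, Ca rises, pH and TN stay flat).
SOIL_MODEL = {
    "pH": (7.3, 0.7, 0),
    "humidity": (3.8, 2.3, -1),
    "TP": (5.9, 6.6, -1),
    "TOC": (1.5, 1.2, -1),
    "TN": (0.66, 0.33, 0),
    "Fe": (15.0, 2.7, -1),
    "Ca": (3000.0, 1600.0, 1),
    "K": (108.0, 55.0, -1),
    "CEC": (7.7, 5.3, -1),
}


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    ``dispersion`` is the Dirichlet-multinomial intraclass correlation
    (0 < theta < 1): the Dirichlet concentration is p * (1-theta)/theta,
    so larger values mean noisier replicate compositions.
    ``fold_change_per_zone`` is the multiplicative abundance step per zone
    of increasing aridity for planted OTUs (>= 1; 1 disables the signal).
    """

    n_otus: int = 300
    n_sites_per_zone: int = 3
    n_samples_per_site_per_compartment: int = 3
    n_planted_increased: int = 10
    n_planted_decreased: int = 10
    fold_change_per_zone: float = 2.0
    sequencing_depth: int = 5000
    dispersion: float = 2e-4
    base_lognormal_sigma: float = 1.5
    min_planted_abundance: float = 0.004
    max_planted_abundance: float = 0.02
    compartment_effect_sigma: float = 0.75
    soil_gradient_strength: float = 0.9
    n_organelle: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_otus, self.n_sites_per_zone,
               self.n_samples_per_site_per_compartment, self.sequencing_depth) < 1:
            raise ValueError("counts must be positive")
        if self.n_planted_increased < 0 or self.n_planted_decreased < 0 or self.n_organelle < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_planted_increased + self.n_planted_decreased + self.n_organelle > self.n_otus:
            raise ValueError("more planted OTUs than n_otus")
        if self.fold_change_per_zone < 1:
            raise ValueError("fold_change_per_zone must be >= 1")
        if not (0 < self.dispersion < 1):
            raise ValueError("dispersion must lie in (0, 1)")
        if not (0 <= abs(self.soil_gradient_strength) <= 1):
            raise ValueError("|soil_gradient_strength| must be <= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-OTU label and per-soil-parameter sign."""

    labels: pd.Series  # otu -> increased / decreased / neutral / organelle
    soil_signs: dict = field(default_factory=dict)


def _make_taxonomy(otu_ids, rng: np.random.Generator, organelle_ids=()) -> pd.DataFrame:
    phyla, pw = zip(*_PHYLA)
    classes, cw = zip(*_PROTEO_CLASSES)
    rows = []
    organelle_ids = set(organelle_ids)
    for otu in otu_ids:
        if otu in organelle_ids:
            rows.append(("Bacteria", "Cyanobacteria", "Chloroplast", "Streptophyta", None, None))
            continue
        phylum = rng.choice(phyla, p=pw)
        if phylum == "Euryarchaeota":
            rows.append(("Archaea", phylum, "Halobacteria", None, None, None))
        elif phylum == "Proteobacteria":
            rows.append(("Bacteria", phylum, rng.choice(classes, p=cw), None, None, None))
        else:
            rows.append(("Bacteria", phylum, None, None, None, None))
    return pd.DataFrame(rows, index=pd.Index(otu_ids, name="otu_id"), columns=list(_io.RANKS))


def generate_dataset(cfg: SyntheticConfig):
    """Generate (counts, metadata, taxonomy, soil, truth), reproducibly.

    Returns
    -------
    counts : DataFrame (OTUs x samples, integer, columns sum to
        ``sequencing_depth``)
    metadata : DataFrame indexed by sample id (compartment, zone,
        zone_rank, site_id)
    taxonomy : DataFrame indexed by OTU id
    soil : DataFrame indexed by site id (nine parameters)
    truth : SyntheticTruth
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    otu_ids = [f"OTU_{i:04d}" for i in range(cfg.n_otus)]

    # --- base composition (heavy-tailed) and planted labels
    base = rng.lognormal(0.0, cfg.base_lognormal_sigma, cfg.n_otus)
    base /= base.sum()
    # per-OTU compartment preference (rhizosphere vs endosphere enrichment)
    comp_pref = {
        comp: rng.lognormal(0.0, cfg.compartment_effect_sigma, cfg.n_otus)
        for comp in _io.COMPARTMENTS
    }
    # Planted responders must be comfortably abundant in BOTH compartments
    # (trend classification is per compartment) but must not dominate the
    # community, or renormalization would flatten everyone's profiles;
    # score by the weaker compartment, cap by the stronger one.
    score = base * np.minimum.reduce(list(comp_pref.values()))
    peak = base * np.maximum.reduce(list(comp_pref.values()))
    eligible = [
        i for i in rng.permutation(cfg.n_otus)
        if score[i] >= cfg.min_planted_abundance and peak[i] <= cfg.max_planted_abundance
    ]
    needed = cfg.n_planted_increased + cfg.n_planted_decreased
    if len(eligible) < needed:  # top up with the next-strongest leftovers
        rest = [i for i in np.argsort(score)[::-1] if i not in set(eligible)]
        eligible = eligible + rest[: needed - len(eligible)]
    planted = eligible[:needed]
    inc_idx = np.array(planted[: cfg.n_planted_increased], dtype=int)
    dec_idx = np.array(planted[cfg.n_planted_increased:], dtype=int)
    neutral_pool = [i for i in range(cfg.n_otus) if i not in set(planted)]
    organelle_idx = np.array(
        sorted(rng.choice(neutral_pool, size=cfg.n_organelle, replace=False))
        if cfg.n_organelle else [], dtype=int,
    )

    labels = pd.Series("neutral", index=otu_ids, name="label")
    labels.iloc[inc_idx] = "increased"
    labels.iloc[dec_idx] = "decreased"
    if len(organelle_idx):
        labels.iloc[organelle_idx] = "organelle"
    taxonomy = _make_taxonomy(otu_ids, rng, organelle_ids=[otu_ids[i] for i in organelle_idx])

    comp_base = {comp: base * comp_pref[comp] for comp in _io.COMPARTMENTS}

    # --- design: sites, samples
    sites, site_zone = [], {}
    for zone in ZONES:
        for j in range(cfg.n_sites_per_zone):
            site = f"{_ZONE_CODE[zone]}{j + 1}"
            sites.append(site)
            site_zone[site] = zone
    meta_rows, sample_ids = [], []
    for site in sites:
        zone = site_zone[site]
        for comp in _io.COMPARTMENTS:
            for r in range(cfg.n_samples_per_site_per_compartment):
                sid = f"{site}_{comp[0]}{r + 1}"
                sample_ids.append(sid)
                meta_rows.append((sid, comp, zone, site))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "compartment", "zone", "site_id"]
    ).set_index("sample_id")
    metadata = _io.validate_metadata(metadata)

    # --- counts
    fold = cfg.fold_change_per_zone
    max_rank = len(ZONES) - 1
    concentration = (1.0 - cfg.dispersion) / cfg.dispersion
    counts = np.zeros((cfg.n_otus, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        zone_rank = int(metadata.loc[sid, "zone_rank"])
        comp = metadata.loc[sid, "compartment"]
        p = comp_base[comp].copy()
        p[inc_idx] *= fold**zone_rank
        p[dec_idx] *= fold ** (max_rank - zone_rank)
        p /= p.sum()
        alpha = p * concentration
        composition = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(cfg.sequencing_depth, composition)
    counts = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids)

    # --- soil covariates
    x = metadata.drop_duplicates("site_id").set_index("site_id")["zone_rank"]
    x = x.reindex(sites).to_numpy(dtype=float)
    x_std = (x - x.mean()) / x.std()
    rho = cfg.soil_gradient_strength
    soil = {}
    signs = {}
    for param in SOIL_COLUMNS:
        mu, sd, sign = SOIL_MODEL[param]
        signs[param] = sign
        noise = rng.standard_normal(len(sites))
        if sign == 0:
            vals = mu + sd * noise
        else:
            vals = mu + sd * (sign * rho * x_std + np.sqrt(1 - rho**2) * noise)
        vals = np.clip(vals, 0.0, None)
        if param in ("humidity", "TOC", "TN"):
            vals = np.clip(vals, 0.0, 100.0)
        soil[param] = vals
    soil = pd.DataFrame(soil, index=pd.Index(sites, name="site_id"))

    return counts, metadata, taxonomy, soil, SyntheticTruth(labels, signs)


def write_dataset(out_dir, cfg: SyntheticConfig):
    """Generate a dataset and write it in the package's TSV formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, metadata, taxonomy, soil, truth = generate_dataset(cfg)
    _io.write_otu_table(counts, out_dir / "otu_table.tsv")
    metadata.drop(columns=["zone_rank"]).to_csv(out_dir / "metadata.tsv", sep="\t")
    _io.write_taxonomy(taxonomy, out_dir / "taxonomy.tsv")
    soil.to_csv(out_dir / "soil.tsv", sep="\t")
    truth.labels.to_frame().to_csv(out_dir / "truth.tsv", sep="\t")
    pd.Series(asdict(cfg)).to_json(out_dir / "config.json", indent=2)
    return out_dir


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str):
    return resources.files("aridinet.data").joinpath(name)


def load_table2_fixture(corrected: bool = False) -> pd.DataFrame:
    """The 19-site reference soil physicochemical table.

    Values are stored exactly as printed in the source survey, including a
    physically impossible humid-zone pH of 74.3 (certainly a typo for
    7.43).  With ``corrected=True`` the pH is replaced by 7.43 and the
    substitution recorded in ``df.attrs["corrections"]``.
    """
    with resources.as_file(_fixture_path("soil_profiles.tsv")) as p:
        soil = _io.read_soil(p)
    if corrected:
        soil = soil.copy()
        soil.loc["BZ", "pH"] = 7.43
        soil.attrs["corrections"] = ["BZ pH 74.3 -> 7.43"]
    return soil


def load_zone_fixture() -> pd.DataFrame:
    """Site -> bioclimatic-zone assignments of the 19 reference sites."""
    with resources.as_file(_fixture_path("site_zones.tsv")) as p:
        sites = pd.read_csv(p, sep="\t", dtype=str).set_index("site_id")
    sites["zone_rank"] = sites["zone"].map(_io.ZONE_RANK).astype(int)
    sites["latitude"] = sites["latitude"].astype(float)
    sites["longitude"] = sites["longitude"].astype(float)
    return sites
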