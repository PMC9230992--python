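"""Synthetic long-term fertilization-experiment generator.

Emulates the data structure of a factorial rice-wheat rotation trial:
4 fertilization regimes (NoF, NPK, M, NPKM) x 2 crop seasons x 2 soil
depths x 3 replicates = 48 samples, each carrying rarefiable bacterial
(16S) and fungal (ITS) OTU count tables, GC peak areas for amino sugars
with internal standards, and soil chemistry (SOC, TN).

The generative model is a linear structural-equation system over latent
variables (design factors -> community axes -> residue pools -> soil
pools).  Every latent is scaled to unit variance with its structural
residual orthogonalized against its parents, so the configured path
coefficients are exactly the true standardized coefficients - the ground
truth the path-model recovery tests check against.  OTU abundances are
log-normal with additive factor shifts realized by multinomial read
sampling at Poisson-distributed depths; one planted fungal "keystone" OTU
has a log-abundance with exactly the configured correlation to the
fungal-residue latent.  Peak areas are back-computed from the true
amino-sugar masses by inverting the internal-standard equation, so
quantification round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .ecology import CountTable
from .plspm import effects_from_matrix
from .residues import MW_GLCN, MW_MURN

#: default true standardized path coefficients of the latent system
DEFAULT_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("inorganic", "bacterial_community"): 0.30,
    ("organic", "bacterial_community"): 0.40,
    ("season", "bacterial_community"): 0.30,
    ("depth", "bacterial_community"): 0.45,
    ("inorganic", "fungal_community"): 0.30,
    ("organic", "fungal_community"): 0.50,
    ("season", "fungal_community"): 0.35,
    ("depth", "fungal_community"): 0.25,
    ("bacterial_community", "bacterial_residue"): 0.60,
    ("fungal_community", "fungal_residue"): 0.60,
    ("bacterial_residue", "soc"): 0.25,
    ("fungal_residue", "soc"): 0.60,
    ("bacterial_residue", "tn"): 0.30,
    ("fungal_residue", "tn"): 0.55,
}

KEYSTONE_TAXONOMY = (
    "Fungi", "Ascomycota", "Pezizomycetes", "Pezizales", "Pyronemataceae", "Pseudaleuria"
)

_BACT_PHYLA = (
    "Proteobacteria", "Acidobacteria", "Actinobacteria", "Chloroflexi",
    "Planctomycetota", "Verrucomicrobia", "Gemmatimonadetes", "Bacteroidetes",
    "Firmicutes", "Nitrospirae",
)
_FUNG_PHYLA = (
    "Ascomycota", "Basidiomycota", "Mortierellomycota", "Glomeromycota",
    "Chytridiomycota", "Rozellomycota",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generative parameters of the synthetic experiment.

    Defaults reproduce the factorial layout of the emulated trial (48
    samples) with read depths that leave rarefaction at 30,000 (16S) /
    25,000 (ITS) something to do.  ``keystone_effect`` is the correlation
    between the planted keystone OTU's log abundance and the fungal-residue
    latent; ``noise_sd`` is the observation-noise standard deviation added
    to soil chemistry, amino-sugar masses and model indicators, while
    ``otu_noise_sd`` is the (much larger) idiosyncratic between-replicate
    variability of OTU log abundances typical of soil communities.
    """

    n_replicates: int = 3
    regimes: tuple[str, ...] = ("NoF", "NPK", "M", "NPKM")
    seasons: tuple[str, ...] = ("rice", "wheat")
    depths: tuple[str, ...] = ("0-10", "10-20")
    n_otus_bacteria: int = 400
    n_otus_fungi: int = 200
    sequencing_depth_mean: int = 40000
    keystone_effect: float = 0.9
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    noise_sd: float = 0.3
    otu_noise_sd: float = 0.6
    base_abundance_sd: float = 1.2
    factor_effect_fraction: float = 0.10
    factor_effect_sd: float = 0.4
    community_fraction: float = 0.25
    community_loading_sd: float = 0.35
    residue_guild_fraction: float = 0.30
    residue_guild_loading_sd: float = 0.60
    keystone_log_mean: float = 2.5
    keystone_log_sd: float = 0.5
    residue_noise_sd: float = 1.0
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.keystone_effect <= 1.0:
            raise ValueError("keystone_effect must be in [0, 1]")
        for name in ("n_replicates", "n_otus_bacteria", "n_otus_fungi",
                     "sequencing_depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        g = nx.DiGraph(list(self.path_coefficients))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path_coefficients must define an acyclic graph")


@dataclass
class GroundTruth:
    """What the generator knows and the analysis is asked to recover."""

    latent_scores: pd.DataFrame  # samples x latents (unit variance)
    path_coefficients: dict[tuple[str, str], float]
    keystone_otu: str
    amino_sugars: pd.DataFrame  # true GlcN/GalN/MurN in g/kg
    keystone_log_abundance: pd.Series


@dataclass
class SyntheticDataset:
    """All tables of one synthetic experiment, sharing one sample index."""

    metadata: pd.DataFrame
    bacteria: CountTable
    fungi: CountTable
    taxonomy: pd.DataFrame
    peak_areas: pd.DataFrame
    soil_chemistry: pd.DataFrame
    ground_truth: GroundTruth


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return v / sd


def _orthogonal_noise(rng: np.random.Generator, basis: np.ndarray) -> np.ndarray:
    """A standardized noise vector orthogonal (in-sample) to the basis columns."""
    n = basis.shape[0]
    e = rng.standard_normal(n)
    e -= e.mean()
    if basis.size:
        q, _ = np.linalg.qr(basis - basis.mean(axis=0, keepdims=True))
        e -= q @ (q.T @ e)
    return _standardize(e)


def correlated_vector(rng: np.random.Generator, z: np.ndarray, rho: float) -> np.ndarray:
    """Standardized vector with exact in-sample correlation ``rho`` to ``z``."""
    zs = _standardize(np.asarray(z, float))
    e = _orthogonal_noise(rng, zs[:, None])
    return rho * zs + np.sqrt(max(0.0, 1.0 - rho**2)) * e


def simulate_latent_scores(
    paths: dict[tuple[str, str], float],
    n: int,
    rng: np.random.Generator,
    exogenous: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Unit-variance latent scores from the structural equations.

    Each endogenous latent is sum(coef * parent) plus a residual drawn
    orthogonal to its parents and scaled so the latent has exactly unit
    sample variance; the configured coefficients are therefore the true
    standardized coefficients.  Exogenous latents are standardized draws
    (or supplied columns, e.g. design dummies).
    """
    exogenous = exogenous or {}
    g = nx.DiGraph(list(paths))
    g.add_nodes_from(exogenous)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path structure must be acyclic")
    scores: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if not parents:
            base = exogenous.get(node, None)
            if base is None:
                base = rng.standard_normal(n)
            scores[node] = _standardize(np.asarray(base, float))
            continue
        systematic = sum(paths[(p, node)] * scores[p] for p in parents)
        basis = np.column_stack([scores[p] for p in parents])
        e = _orthogonal_noise(rng, basis)
        resid_var = max(1.0 - systematic.var(), 0.0025)
        scores[node] = _standardize(systematic + np.sqrt(resid_var) * e)
    return pd.DataFrame(scores)


def _banded_loadings(
    rng: np.random.Generator, n: int, fraction: float, scale: float
) -> np.ndarray:
    """Latent loadings for a random subset of OTUs: random sign, magnitude
    uniform in [0.95, 1.05] x scale.

    The narrow magnitude band keeps within-guild coupling homogeneous, so
    no single guild member dwarfs the others the way heavy-tailed normal
    loadings would.
    """
    out = np.zeros(n)
    hit = rng.random(n) < fraction
    k = int(hit.sum())
    out[hit] = rng.choice([-1.0, 1.0], size=k) * scale * rng.uniform(0.95, 1.05, size=k)
    return out


def _log_abundances(
    rng: np.random.Generator,
    n_otus: int,
    design: np.ndarray,  # samples x factors, binary 0/1
    community_latent: np.ndarray,  # unit-variance community score per sample
    residue_latent: np.ndarray,  # unit-variance residue score per sample
    config: SimulationConfig,
) -> np.ndarray:
    """Log-normal latent log abundances (OTUs x samples).

    Each OTU combines a static base abundance, direct additive shifts from
    a fraction of the design factors, a loading on the marker's community
    latent (the mediated fertilization/season/depth response), and
    idiosyncratic replicate noise.  A smaller "residue guild" of taxa
    additionally tracks the marker's residue latent - the taxa whose
    biomass turnover feeds the necromass pool co-vary with it.
    """
    n_samples, n_factors = design.shape
    base = rng.normal(0.0, config.base_abundance_sd, size=n_otus)
    coefs = np.zeros((n_otus, n_factors))
    for f in range(n_factors):
        hit = rng.random(n_otus) < config.factor_effect_fraction
        coefs[hit, f] = rng.normal(0.0, config.factor_effect_sd, size=int(hit.sum()))
    loadings = _banded_loadings(
        rng, n_otus, config.community_fraction, config.community_loading_sd
    )
    guild = _banded_loadings(
        rng, n_otus, config.residue_guild_fraction, config.residue_guild_loading_sd
    )
    la = base[:, None] + coefs @ design.T + loadings[:, None] * community_latent[None, :]
    la += guild[:, None] * residue_latent[None, :]
    la += config.otu_noise_sd * rng.standard_normal((n_otus, n_samples))
    if config.zero_inflation > 0:
        knocked = rng.random((n_otus, n_samples)) < config.zero_inflation
        la = np.where(knocked, -np.inf, la)
    return la


def _counts_from_log_abundance(
    rng: np.random.Generator, la: np.ndarray, depth_mean: int
) -> np.ndarray:
    """Multinomial read sampling at Poisson depths; returns OTUs x samples."""
    n_otus, n_samples = la.shape
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = np.exp(la[:, j] - la[:, j].max())
        p = w / w.sum()
        depth = rng.poisson(depth_mean)
        counts[:, j] = rng.multinomial(depth, p)
    return counts


def _taxonomy(
    rng: np.random.Generator, otu_ids: list[str], phyla: tuple[str, ...], kingdom: str
) -> pd.DataFrame:
    rows = []
    for otu in otu_ids:
        ph = phyla[rng.integers(len(phyla))]
        rows.append(
            {
                "kingdom": kingdom,
                "phylum": ph,
                "class": f"{ph}_cls{rng.integers(1, 4)}",
                "order": f"{ph}_ord{rng.integers(1, 6)}",
                "family": f"{ph}_fam{rng.integers(1, 9)}",
                "genus": f"{ph}_gen{rng.integers(1, 15)}",
            }
        )
    return pd.DataFrame(rows, index=pd.Index(otu_ids, name="otu_id"))


# instrument constants of the emulated GC protocol
INOSITOL_MASS_UG = 100.0
NMEG_MASS_UG = 100.0
DRY_MASS_G = 0.5
BASE_INOSITOL_AREA = 1.2e5


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one complete synthetic experiment.

    Deterministic given ``config.seed``; all tables share the same sample
    ids.  See the module docstring for the generative model.
    """
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("latents", "bacteria", "fungi", "keystone", "peaks", "chem", "taxonomy"),
            root.spawn(7),
        )
    }

    rows = []
    for season in config.seasons:
        for depth in config.depths:
            for regime in config.regimes:
                for rep in range(1, config.n_replicates + 1):
                    sid = (
                        f"{season[:1].upper()}{'T' if depth == config.depths[0] else 'B'}"
                        f"_{regime}_r{rep}"
                    )
                    rows.append(
                        {
                            "sample_id": sid,
                            "regime": regime,
                            "season": season,
                            "depth": depth,
                            "replicate": rep,
                            "inorganic": int(regime in ("NPK", "NPKM")),
                            "organic": int(regime in ("M", "NPKM")),
                        }
                    )
    metadata = pd.DataFrame(rows).set_index("sample_id")
    n = len(metadata)
    samples = metadata.index

    design_cols = {
        "inorganic": metadata["inorganic"].to_numpy(float),
        "organic": metadata["organic"].to_numpy(float),
        "season": (metadata["season"] == config.seasons[-1]).to_numpy(float),
        "depth": (metadata["depth"] == config.depths[-1]).to_numpy(float),
    }
    latents = simulate_latent_scores(
        config.path_coefficients, n, streams["latents"], exogenous=design_cols
    )
    latents.index = samples

    # planted keystone: fungal OTU 1, log abundance with exact correlation
    # keystone_effect to the fungal-residue latent, placed near the top of
    # the abundance distribution so read sampling barely attenuates it.
    # The fungal residue guild tracks the keystone's abundance itself (a
    # keystone taxon structures the taxa around it), so the guild also
    # co-varies with the residue latent through the keystone.
    z_fr = latents["fungal_residue"].to_numpy()
    key = correlated_vector(streams["keystone"], z_fr, config.keystone_effect)

    binary_design = np.column_stack(list(design_cols.values()))
    la_b = _log_abundances(
        streams["bacteria"], config.n_otus_bacteria, binary_design,
        latents["bacterial_community"].to_numpy(),
        latents["bacterial_residue"].to_numpy(), config,
    )
    la_f = _log_abundances(
        streams["fungi"], config.n_otus_fungi, binary_design,
        latents["fungal_community"].to_numpy(), key, config,
    )
    la_f[0, :] = config.keystone_log_mean + config.keystone_log_sd * key

    counts_b = _counts_from_log_abundance(streams["bacteria"], la_b, config.sequencing_depth_mean)
    counts_f = _counts_from_log_abundance(streams["fungi"], la_f, config.sequencing_depth_mean)
    b_ids = [f"B_OTU{i + 1:04d}" for i in range(config.n_otus_bacteria)]
    f_ids = [f"F_OTU{i + 1:04d}" for i in range(config.n_otus_fungi)]
    sample_cols = pd.Index(list(samples))  # unnamed, for clean TSV round-trips
    bacteria = CountTable(pd.DataFrame(counts_b, index=b_ids, columns=sample_cols), marker="16S")
    fungi = CountTable(pd.DataFrame(counts_f, index=f_ids, columns=sample_cols), marker="ITS")

    tax_b = _taxonomy(streams["taxonomy"], b_ids, _BACT_PHYLA, "Bacteria")
    tax_f = _taxonomy(streams["taxonomy"], f_ids, _FUNG_PHYLA, "Fungi")
    tax_f.loc[f_ids[0]] = KEYSTONE_TAXONOMY
    taxonomy = pd.concat([tax_b, tax_f])

    # true amino-sugar masses (g/kg dry soil), log-linear in the residue latents
    # residue pools integrate years of turnover: plot-to-plot variability
    # around the latent is substantial (residue_noise_sd on the log scale)
    rng_p = streams["peaks"]
    z_br = latents["bacterial_residue"].to_numpy()
    murn = 0.030 * np.exp(0.20 * (z_br + config.residue_noise_sd * rng_p.standard_normal(n)))
    fungal_glcn = 0.55 * np.exp(
        0.25 * (z_fr + config.residue_noise_sd * rng_p.standard_normal(n))
    )
    glcn = fungal_glcn + 2.0 * murn * MW_GLCN / MW_MURN
    galn = 0.4 * glcn * np.exp(0.1 * config.noise_sd * rng_p.standard_normal(n))
    amino = pd.DataFrame({"GlcN": glcn, "GalN": galn, "MurN": murn}, index=samples)

    # peak areas: invert m_x = m_i * (A_x / A_i) * Rf  (Rf = 1)
    a_i = BASE_INOSITOL_AREA * np.exp(0.05 * rng_p.standard_normal(n))
    peak = {"area_inositol": a_i}
    for analyte in ("GlcN", "GalN", "MurN"):
        m_x_ug = amino[analyte].to_numpy() * 1000.0 * DRY_MASS_G
        peak[f"area_{analyte.lower()}"] = a_i * m_x_ug / INOSITOL_MASS_UG
    recovery = np.clip(0.97 + 0.01 * rng_p.standard_normal(n), 0.8, 1.1)
    peak["area_nmeg"] = a_i * recovery * NMEG_MASS_UG / INOSITOL_MASS_UG
    peak["mass_inositol_ug"] = np.full(n, INOSITOL_MASS_UG)
    peak["dry_mass_g"] = np.full(n, DRY_MASS_G)
    peak_areas = pd.DataFrame(peak, index=samples)

    rng_c = streams["chem"]
    soc = 14.5 + 3.0 * latents["soc"].to_numpy() + config.noise_sd * 0.5 * rng_c.standard_normal(n)
    tn = 1.9 + 0.30 * latents["tn"].to_numpy() + config.noise_sd * 0.05 * rng_c.standard_normal(n)
    soil = pd.DataFrame(
        {"SOC": np.clip(soc, 2.0, None), "TN": np.clip(tn, 0.2, None)}, index=samples
    )

    truth = GroundTruth(
        latent_scores=latents,
        path_coefficients=dict(config.path_coefficients),
        keystone_otu=f_ids[0],
        amino_sugars=amino,
        keystone_log_abundance=pd.Series(la_f[0, :], index=samples),
    )
    return SyntheticDataset(
        metadata=metadata,
        bacteria=bacteria,
        fungi=fungi,
        taxonomy=taxonomy,
        peak_areas=peak_areas,
        soil_chemistry=soil,
        ground_truth=truth,
    )


def ground_truth_effects(dataset: SyntheticDataset) -> pd.DataFrame:
    """True direct/indirect/total effects implied by the planted coefficients.

    Indirect effects sum products of coefficients over all directed latent
    paths; total = direct + indirect.  Empty for an empty path set.
    """
    if dataset.ground_truth is None:
        raise ValueError("dataset has no ground truth")
    coefs = dataset.ground_truth.path_coefficients
    nodes = sorted({x for pair in coefs for x in pair})
    mat = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for (s, t), c in coefs.items():
        mat.loc[s, t] = c
    return effects_from_matrix(mat)


def simulate_indicator_data(
    paths: dict[tuple[str, str], float],
    n: int,
    noise_sd: float,
    n_indicators: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Latent SEM draw plus noisy reflective indicators, for path-model tests.

    Each latent gets ``n_indicators`` indicators equal to the latent plus
    N(0, noise_sd) observation noise.  Returns (indicator table, block
    mapping, true latent scores).
    """
    rng = np.random.default_rng(seed)
    latents = simulate_latent_scores(paths, n, rng)
    data = {}
    blocks: dict[str, list[str]] = {}
    for name in latents.columns:
        blocks[name] = []
        for i in range(n_indicators):
            col = f"{name}_x{i + 1}"
            data[col] = latents[name].to_numpy() + noise_sd * rng.standard_normal(n)
            blocks[name].append(col)
    return pd.DataFrame(data), blocks, latents


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
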