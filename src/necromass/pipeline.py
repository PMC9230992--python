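"""End-to-end orchestration: residues -> rarefaction -> ordination ->
distance statistics -> network -> path model.

Each stage records status, wall-clock time and warnings in a
:class:`RunReport`; any failure aborts the run with the stage named.  All
randomness derives from one root seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, io, network as net_mod, plspm, residues as res_mod
from .simulate import SyntheticDataset

PLSPM_LATENTS = [
    "inorganic", "organic", "season", "depth",
    "bacterial_community", "fungal_community",
    "bacterial_residue", "fungal_residue", "soc", "tn",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, depths, permutation counts and seeds for a full run."""

    input_dir: str | Path | None = None  # dataset directory (io.write_dataset layout)
    output_dir: str | Path = "results"
    rarefaction_depth_16s: int = 30000
    rarefaction_depth_its: int = 25000
    permanova_permutations: int = 9999
    ordination_permutations: int = 999
    network_top_k: int = 500
    network_rho: float = 0.5
    network_p: float = 0.05
    bootstrap_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth_16s <= 0 or self.rarefaction_depth_its <= 0:
            raise ValueError("rarefaction depths must be positive")


@dataclass
class StageReport:
    name: str
    status: str
    seconds: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    """Per-stage status plus the output-file manifest of a pipeline run."""

    stages: list[StageReport] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "parameters": self.parameters,
            "stages": [
                {"name": s.name, "status": s.status, "seconds": round(s.seconds, 3),
                 "warnings": s.warnings}
                for s in self.stages
            ],
            "manifest": self.manifest,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_path_model(indicators: pd.DataFrame) -> plspm.PathModelSpec:
    """The fertilization -> microbiome -> residues -> soil C/N path model.

    Design factors are single-indicator binary blocks; community blocks are
    the first two principal-coordinate axes; residue blocks pair the C and
    N pools; SOC and TN close the chain.
    """
    blocks = {
        "inorganic": ["inorganic"],
        "organic": ["organic"],
        "season": ["season_wheat"],
        "depth": ["depth_lower"],
        "bacterial_community": ["BPC1", "BPC2"],
        "fungal_community": ["FPC1", "FPC2"],
        "bacterial_residue": ["BRC", "BRN"],
        "fungal_residue": ["FRC", "FRN"],
        "soc": ["SOC"],
        "tn": ["TN"],
    }
    paths = [
        *[(f, c) for f in ("inorganic", "organic", "season", "depth")
          for c in ("bacterial_community", "fungal_community")],
        ("bacterial_community", "bacterial_residue"),
        ("fungal_community", "fungal_residue"),
        ("bacterial_residue", "soc"),
        ("fungal_residue", "soc"),
        ("bacterial_residue", "tn"),
        ("fungal_residue", "tn"),
    ]
    missing = [c for cols in blocks.values() for c in cols if c not in indicators.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    return plspm.PathModelSpec(blocks=blocks, paths=paths)


def run_pipeline(
    config: PipelineConfig, dataset: SyntheticDataset | None = None
) -> RunReport:
    """Execute the full analysis; returns the run report.

    ``dataset`` may be passed in memory; otherwise ``config.input_dir`` is
    read.  Outputs land in ``config.output_dir`` (created if needed).
    """
    if dataset is None:
        if config.input_dir is None:
            raise ValueError("either dataset or config.input_dir is required")
        dataset = io.read_dataset(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters={
        k: str(getattr(config, k)) for k in (
            "rarefaction_depth_16s", "rarefaction_depth_its",
            "permanova_permutations", "ordination_permutations",
            "network_top_k", "network_rho", "network_p",
            "bootstrap_replicates", "seed",
        )
    })
    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)]
    state: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                warnings = fn() or []
            except Exception as exc:
                report.stages.append(
                    StageReport(name, f"failed: {exc}", time.perf_counter() - t0)
                )
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report.stages.append(StageReport(name, "ok", time.perf_counter() - t0, warnings))
        return wrap

    @stage("residues")
    def _residues():
        warnings = []
        profile = res_mod.quantify_amino_sugars(
            dataset.peak_areas, nmeg_expected_ug=100.0
        )
        resid = res_mod.residues_from_amino_sugars(profile.drop(columns="recovery", errors="ignore"))
        n_clamped = int(resid["clamped"].sum())
        if n_clamped:
            warnings.append(f"fungal GlcN clamped to 0 in {n_clamped} sample(s)")
        ratios = res_mod.contribution_ratios(resid, dataset.soil_chemistry)
        table2 = pd.concat([dataset.soil_chemistry, resid.drop(columns="clamped"), ratios], axis=1)
        io.write_table(profile, outdir / "amino_sugars.tsv")
        io.write_table(table2, outdir / "residue_table.tsv")
        report.manifest["amino_sugars"] = str(outdir / "amino_sugars.tsv")
        report.manifest["residue_table"] = str(outdir / "residue_table.tsv")
        state["residues"] = resid
        state["table2"] = table2
        return warnings

    @stage("rarefaction")
    def _rarefy():
        warnings = []
        for attr, depth, seed, name in (
            ("bacteria", config.rarefaction_depth_16s, seeds[0], "otu_16s_rarefied"),
            ("fungi", config.rarefaction_depth_its, seeds[1], "otu_its_rarefied"),
        ):
            table = getattr(dataset, attr)
            rare = ecology.rarefy(table, depth, seed)
            dropped = set(table.sample_ids) - set(rare.sample_ids)
            if dropped:
                warnings.append(f"{attr}: dropped {sorted(dropped)} below depth {depth}")
            io.write_count_table(rare, outdir / f"{name}.tsv")
            report.manifest[name] = str(outdir / f"{name}.tsv")
            state[f"rare_{attr}"] = rare
        return warnings

    @stage("ordination")
    def _ordination():
        for attr, prefix in (("bacteria", "B"), ("fungi", "F")):
            rare = state[f"rare_{attr}"]
            d = ecology.bray_curtis(rare)
            ord_ = ecology.pcoa(d)
            coords = ord_.coordinates.iloc[:, :2]
            coords.columns = [f"{prefix}PC1", f"{prefix}PC2"]
            state[f"bray_{attr}"] = d
            state[f"pcoa_{attr}"] = coords
            io.write_table(coords, outdir / f"pcoa_{attr}.tsv")
            report.manifest[f"pcoa_{attr}"] = str(outdir / f"pcoa_{attr}.tsv")

    @stage("distance_stats")
    def _stats():
        meta = dataset.metadata.loc[state["bray_bacteria"].index]
        tables = []
        for attr in ("bacteria", "fungi"):
            d = state[f"bray_{attr}"]
            res = ecology.permanova(
                d, meta, ["depth", "season", "regime"],
                n_perm=config.permanova_permutations, seed=seeds[2],
            )
            t = res.table.copy()
            t.insert(0, "community", attr)
            tables.append(t.reset_index())
            disp = ecology.beta_dispersion(
                d, meta["regime"], n_perm=config.ordination_permutations, seed=seeds[3]
            )
            tables.append(pd.DataFrame([{
                "community": attr, "term": "dispersion:regime",
                "pseudo_F": disp.f, "p": disp.p,
            }]))
        io.write_table(pd.concat(tables, ignore_index=True), outdir / "permanova.tsv")
        report.manifest["permanova"] = str(outdir / "permanova.tsv")

        vpa_rows = []
        for attr in ("bacteria", "fungi"):
            vp = ecology.variance_partition(
                state[f"bray_{attr}"], meta,
                {"inorganic": ["inorganic"], "organic": ["organic"],
                 "rotation": ["season"], "depth": ["depth"]},
            )
            row = vp.fractions()
            row["community"] = attr
            vpa_rows.append(row)
        io.write_table(pd.DataFrame(vpa_rows).set_index("community"), outdir / "vpa.tsv")
        report.manifest["vpa"] = str(outdir / "vpa.tsv")

        soil_vars = pd.concat(
            [dataset.soil_chemistry, state["residues"].drop(columns="clamped")], axis=1
        )
        rows = []
        for attr in ("bacteria", "fungi"):
            d = state[f"bray_{attr}"]
            for var in soil_vars.columns:
                r = ecology.dbrda_single(
                    d, soil_vars[var], n_perm=config.ordination_permutations, seed=seeds[4]
                )
                rows.append({"community": attr, "variable": var,
                             "F": r.f, "R2": r.r2, "p": r.p})
        io.write_table(pd.DataFrame(rows).set_index(["community", "variable"]),
                       outdir / "dbrda.tsv")
        report.manifest["dbrda"] = str(outdir / "dbrda.tsv")
        state["soil_vars"] = soil_vars

    @stage("network")
    def _network():
        warnings = []
        spec = net_mod.NetworkSpec(
            top_k=config.network_top_k, rho_threshold=config.network_rho,
            p_threshold=config.network_p,
        )
        rare = state["rare_fungi"]
        top = net_mod.select_top_otus(rare, spec.top_k)
        rel = (top / top.sum(axis=0)).T  # samples x OTUs
        net = net_mod.build_network(
            rel, state["soil_vars"].loc[rel.index], spec, taxonomy=dataset.taxonomy
        )
        if net.excluded:
            warnings.append(f"excluded zero-variance series: {net.excluded}")
        cent = net_mod.centralities(net)
        keys = net_mod.identify_keystones(cent)
        if keys.rule == "fallback":
            warnings.append("keystone rule fell back to mean normalized score")
        net_mod.export_network(
            net, cent, str(outdir / "network_fungi.graphml"), str(outdir / "network_fungi_edges.csv")
        )
        io.write_table(cent, outdir / "network_fungi_centrality.tsv")
        (outdir / "keystone.json").write_text(json.dumps(
            {"keystones": keys.keystones, "rule": keys.rule,
             "taxonomy": {
                 k: ";".join(map(str, dataset.taxonomy.loc[k]))
                 for k in keys.keystones if k in dataset.taxonomy.index
             }},
            indent=1, sort_keys=True,
        ))
        for key in ("network_fungi", "network_fungi_edges", "network_fungi_centrality"):
            ext = {"network_fungi": ".graphml", "network_fungi_edges": ".csv",
                   "network_fungi_centrality": ".tsv"}[key]
            report.manifest[key] = str(outdir / f"{key}{ext}")
        report.manifest["keystone"] = str(outdir / "keystone.json")
        state["keystones"] = keys.keystones
        return warnings

    @stage("plspm")
    def _plspm():
        meta = dataset.metadata
        indicators = pd.DataFrame(index=meta.index)
        indicators["inorganic"] = meta["inorganic"].astype(float)
        indicators["organic"] = meta["organic"].astype(float)
        indicators["season_wheat"] = (meta["season"] == "wheat").astype(float)
        indicators["depth_lower"] = (meta["depth"] != meta["depth"].iloc[0]).astype(float)
        indicators = indicators.join(state["pcoa_bacteria"]).join(state["pcoa_fungi"])
        indicators = indicators.join(state["soil_vars"])
        indicators = indicators.dropna()
        spec = default_path_model(indicators)
        fit = plspm.fit_plspm(indicators, spec)
        effects = plspm.total_effects(fit)
        boot = plspm.bootstrap_plspm(
            indicators, spec, n_boot=config.bootstrap_replicates, seed=seeds[5]
        )
        io.write_table(effects.set_index(["source", "target"]), outdir / "plspm_effects.tsv")
        io.write_table(boot.paths.set_index(["source", "target"]), outdir / "plspm_bootstrap.tsv")
        (outdir / "plspm.json").write_text(json.dumps(
            {
                "gof": fit.gof,
                "r2": fit.r2,
                "n_iterations": fit.n_iterations,
                "path_coefficients": {
                    f"{s}->{t}": float(fit.path_coefficients.loc[s, t])
                    for s, t in spec.paths
                },
            },
            indent=1, sort_keys=True,
        ))
        report.manifest["plspm_effects"] = str(outdir / "plspm_effects.tsv")
        report.manifest["plspm_bootstrap"] = str(outdir / "plspm_bootstrap.tsv")
        report.manifest["plspm"] = str(outdir / "plspm.json")
        state["plspm"] = fit

    report.to_json(outdir / "run_report.json")
    report.manifest["run_report"] = str(outdir / "run_report.json")
    return report
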