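"""Readers and writers for the pipeline's table formats.

All tables are UTF-8.  OTU tables, taxonomy, metadata and statistical
outputs are tab-separated; peak areas are CSV in long instrument-export
form (sample_id, analyte, area, plus per-sample standard mass and dry
mass); ground truth goes to JSON.  Error messages use 1-based row numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecology import CountTable
from .simulate import GroundTruth, SyntheticDataset

FLOAT_FORMAT = "%.10g"

PEAK_ANALYTE_COLUMNS = {
    "GlcN": "area_glcn",
    "GalN": "area_galn",
    "MurN": "area_murn",
    "inositol": "area_inositol",
    "N-methylglucamine": "area_nmeg",
}


def read_count_table(path: str | Path, marker: str = "") -> CountTable:
    """Read an OTU x sample TSV (first column OTU id, header row of samples).

    Rejects duplicate ids, non-integer cells and negative counts with
    messages naming the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate OTU id(s): {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-integer count {df.iat[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    if (numeric < 0).any().any():
        r, c = np.argwhere((numeric < 0).to_numpy())[0]
        raise ValueError(
            f"{path}: negative count {df.iat[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    out = numeric.astype(np.int64)
    out.index.name = None
    return CountTable(out, marker=marker)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.rename_axis("otu_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: otu_id + semicolon-delimited lineage column."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ranks = ["kingdom", "phylum", "class", "order", "family", "genus"]
    parts = df["lineage"].str.split(";", expand=True)
    parts.columns = ranks[: parts.shape[1]]
    return parts


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    lineage = taxonomy.apply(lambda r: ";".join(str(v) for v in r), axis=1)
    lineage.rename("lineage").rename_axis("otu_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def read_peak_areas(path: str | Path) -> pd.DataFrame:
    """Read a long-form peak-area CSV into the wide per-sample table used by
    quantification (columns area_<analyte>, area_inositol, area_nmeg,
    mass_inositol_ug, dry_mass_g)."""
    long = pd.read_csv(path)
    required = {"sample_id", "analyte", "area"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: peak CSV needs columns {sorted(required)}")
    unknown = set(long["analyte"]) - set(PEAK_ANALYTE_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown analyte(s) {sorted(unknown)}")
    wide = long.pivot_table(index="sample_id", columns="analyte", values="area").rename(
        columns=PEAK_ANALYTE_COLUMNS
    )
    for extra in ("mass_inositol_ug", "dry_mass_g"):
        if extra in long.columns:
            wide[extra] = long.groupby("sample_id")[extra].first()
    wide = wide.reindex(long["sample_id"].drop_duplicates())  # file order
    wide.columns.name = None
    return wide


def write_peak_areas(peaks: pd.DataFrame, path: str | Path) -> None:
    inv = {v: k for k, v in PEAK_ANALYTE_COLUMNS.items()}
    rows = []
    for sid, row in peaks.iterrows():
        for col, analyte in inv.items():
            if col in peaks.columns:
                rows.append(
                    {
                        "sample_id": sid,
                        "analyte": analyte,
                        "area": row[col],
                        "mass_inositol_ug": row.get("mass_inositol_ug", np.nan),
                        "dry_mass_g": row.get("dry_mass_g", np.nan),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_soil_chemistry(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_soil_chemistry(chem: pd.DataFrame, path: str | Path) -> None:
    chem.rename_axis("sample_id").to_csv(path, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic TSV output with a stable float format (byte-reproducible)."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic dataset; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "metadata": outdir / "metadata.tsv",
        "bacteria": outdir / "otu_16s.tsv",
        "fungi": outdir / "otu_its.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "peak_areas": outdir / "peak_areas.csv",
        "soil_chemistry": outdir / "soil_chemistry.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_metadata(dataset.metadata, manifest["metadata"])
    write_count_table(dataset.bacteria, manifest["bacteria"])
    write_count_table(dataset.fungi, manifest["fungi"])
    write_taxonomy(dataset.taxonomy, manifest["taxonomy"])
    write_peak_areas(dataset.peak_areas, manifest["peak_areas"])
    write_soil_chemistry(dataset.soil_chemistry, manifest["soil_chemistry"])
    gt = dataset.ground_truth
    payload = {
        "keystone_otu": gt.keystone_otu,
        "path_coefficients": {f"{s}->{t}": c for (s, t), c in gt.path_coefficients.items()},
        "latent_scores": gt.latent_scores.round(12).to_dict(orient="index"),
        "amino_sugars": gt.amino_sugars.round(12).to_dict(orient="index"),
        "keystone_log_abundance": gt.keystone_log_abundance.round(12).to_dict(),
    }
    manifest["ground_truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return manifest


def read_dataset(indir: str | Path) -> SyntheticDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    indir = Path(indir)
    gt_path = indir / "ground_truth.json"
    truth = None
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        truth = GroundTruth(
            latent_scores=pd.DataFrame.from_dict(raw["latent_scores"], orient="index"),
            path_coefficients={
                tuple(k.split("->")): v for k, v in raw["path_coefficients"].items()
            },
            keystone_otu=raw["keystone_otu"],
            amino_sugars=pd.DataFrame.from_dict(raw["amino_sugars"], orient="index"),
            keystone_log_abundance=pd.Series(raw["keystone_log_abundance"]),
        )
    return SyntheticDataset(
        metadata=read_metadata(indir / "metadata.tsv"),
        bacteria=read_count_table(indir / "otu_16s.tsv", marker="16S"),
        fungi=read_count_table(indir / "otu_its.tsv", marker="ITS"),
        taxonomy=read_taxonomy(indir / "taxonomy.tsv"),
        peak_areas=read_peak_areas(indir / "peak_areas.csv"),
        soil_chemistry=read_soil_chemistry(indir / "soil_chemistry.csv"),
        ground_truth=truth,
    )
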