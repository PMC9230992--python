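"""Amino-sugar quantification and microbial-residue carbon/nitrogen conversion.

Amino sugars hydrolysed from soil are biomarkers of dead microbial biomass
(necromass).  Muramic acid (MurN) occurs only in bacterial peptidoglycan and
proxies bacterial residues; glucosamine (GlcN) derives mainly from fungal
chitin once its bacterial share (2 mol GlcN per mol MurN) is removed.
This module converts gas-chromatography peak areas into amino-sugar masses
per kg dry soil (internal-standard quantification), converts those masses
into bacterial/fungal residue C and N pools, expresses the pools as
percentage contributions to soil organic carbon (SOC) and total nitrogen
(TN), and compares treatment groups with one-way ANOVA followed by Fisher's
least-significant-difference test with a compact-letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

ANALYTES = ("GlcN", "GalN", "MurN")

#: molecular weights (g/mol) and residue conversion coefficients
MW_GLCN = 179.17
MW_MURN = 251.23
BRC_PER_MURN = 45.0
BRN_PER_MURN = 6.67
FRC_PER_FUNGAL_GLCN = 9.0
FRN_PER_FUNGAL_GLCN = 1.4


@dataclass(frozen=True)
class ConversionConstants:
    """Coefficients converting amino-sugar masses to residue C/N pools.

    Defaults are the standard literature values: 45 g BRC and 6.67 g BRN per
    g MurN, 9 g FRC and 1.4 g FRN per g fungal GlcN, with the molecular
    weights of GlcN (179.17) and MurN (251.23) used for the stoichiometric
    removal of bacterial GlcN.
    """

    brc_per_murn: float = BRC_PER_MURN
    brn_per_murn: float = BRN_PER_MURN
    frc_per_fungal_glcn: float = FRC_PER_FUNGAL_GLCN
    frn_per_fungal_glcn: float = FRN_PER_FUNGAL_GLCN
    mw_glcn: float = MW_GLCN
    mw_murn: float = MW_MURN


@dataclass(frozen=True)
class ResponseFactors:
    """Detector response factors relative to the myo-inositol standard.

    ``Rf = 1`` reduces quantification to plain area-ratio scaling, which is
    appropriate when the detector responds uniformly; calibrated values from
    pure standards can be supplied per analyte.
    """

    factors: Mapping[str, float] = field(
        default_factory=lambda: {a: 1.0 for a in ANALYTES}
    )

    def __post_init__(self) -> None:
        for name, rf in self.factors.items():
            if not rf > 0:
                raise ValueError(f"response factor for {name} must be > 0, got {rf}")

    def __getitem__(self, analyte: str) -> float:
        try:
            return self.factors[analyte]
        except KeyError:
            raise KeyError(f"no response factor for analyte {analyte!r}") from None


def quantify_amino_sugars(
    peaks: pd.DataFrame,
    rf: ResponseFactors | None = None,
    *,
    nmeg_expected_ug: float | None = None,
) -> pd.DataFrame:
    """Convert GC peak areas to amino-sugar masses in g per kg dry soil.

    ``peaks`` is a wide per-sample table (index = sample id) with columns
    ``area_<analyte>`` for GlcN/GalN/MurN, ``area_inositol`` (first internal
    standard), ``mass_inositol_ug`` (its added mass), ``dry_mass_g`` (soil
    analysed) and optionally ``area_nmeg`` (N-methylglucamine, the recovery
    standard added before derivatization).

    For each analyte, mass on column = m_i * (A_x / A_i) * Rf_x; dividing by
    the dry soil mass gives ug/g, i.e. mg/kg, converted to g/kg.  When
    ``nmeg_expected_ug`` is given and an N-methylglucamine area is present,
    a ``recovery`` column (observed/expected, area-ratio based) is added.
    """
    rf = rf or ResponseFactors()
    required = ["area_inositol", "mass_inositol_ug", "dry_mass_g"]
    for col in required:
        if col not in peaks.columns:
            raise ValueError(f"peak table missing required column {col!r}")
    a_i = peaks["area_inositol"].to_numpy(float)
    if np.any(a_i <= 0):
        bad = peaks.index[a_i <= 0].tolist()
        raise ValueError(f"internal-standard area must be > 0 (samples {bad})")
    m_i = peaks["mass_inositol_ug"].to_numpy(float)
    dry = peaks["dry_mass_g"].to_numpy(float)
    if np.any(dry <= 0):
        raise ValueError("dry mass must be > 0")

    out = {}
    for analyte in ANALYTES:
        col = f"area_{analyte.lower()}"
        if col not in peaks.columns:
            raise ValueError(f"peak table missing column {col!r}")
        a_x = peaks[col].to_numpy(float)
        if np.any(a_x < 0):
            raise ValueError(f"negative peak area for {analyte}")
        mass_ug = m_i * (a_x / a_i) * rf[analyte]
        out[analyte] = mass_ug / dry / 1000.0  # ug/g -> g/kg
    profile = pd.DataFrame(out, index=peaks.index)
    if nmeg_expected_ug is not None and "area_nmeg" in peaks.columns:
        observed_ug = m_i * (peaks["area_nmeg"].to_numpy(float) / a_i)
        profile["recovery"] = observed_ug / nmeg_expected_ug
    return profile


def residues_from_amino_sugars(
    profile: pd.DataFrame, constants: ConversionConstants | None = None
) -> pd.DataFrame:
    """Convert amino-sugar masses (g/kg) to residue C/N pools (g/kg).

    BRC = MurN*45 and BRN = MurN*6.67.  Fungal GlcN is the molar excess of
    GlcN over twice the MurN molar content, converted back to mass:
    fungal_GlcN = (GlcN/179.17 - 2*MurN/251.23)*179.17; FRC = fungal_GlcN*9
    and FRN = fungal_GlcN*1.4.  A negative fungal GlcN (bacteria-dominated
    samples with measurement noise) is clamped to zero and flagged in the
    boolean ``clamped`` column rather than raising.
    """
    c = constants or ConversionConstants()
    murn = profile["MurN"].to_numpy(float)
    glcn = profile["GlcN"].to_numpy(float)
    if np.any(murn < 0) or np.any(glcn < 0):
        raise ValueError("amino-sugar masses must be non-negative")
    fungal_glcn = (glcn / c.mw_glcn - 2.0 * murn / c.mw_murn) * c.mw_glcn
    clamped = fungal_glcn < 0
    fungal_glcn = np.where(clamped, 0.0, fungal_glcn)
    return pd.DataFrame(
        {
            "BRC": murn * c.brc_per_murn,
            "BRN": murn * c.brn_per_murn,
            "FRC": fungal_glcn * c.frc_per_fungal_glcn,
            "FRN": fungal_glcn * c.frn_per_fungal_glcn,
            "clamped": clamped,
        },
        index=profile.index,
    )


RATIO_COLUMNS = ("BRC/SOC", "BRN/TN", "FRC/SOC", "FRN/TN")


def contribution_ratios(residues: pd.DataFrame, chem: pd.DataFrame) -> pd.DataFrame:
    """Percent contributions of residue pools to soil C and N pools.

    Each ratio is 100 * residue / pool; values are kept at full precision
    (rounding to one decimal is a rendering concern).  ``chem`` must carry
    SOC and TN (g/kg) for exactly the samples in ``residues``.
    """
    if set(residues.index) != set(chem.index):
        missing = residues.index.symmetric_difference(chem.index).tolist()
        raise ValueError(f"sample mismatch between residues and soil chemistry: {missing}")
    chem = chem.loc[residues.index]
    soc = chem["SOC"].to_numpy(float)
    tn = chem["TN"].to_numpy(float)
    if np.any(soc <= 0) or np.any(tn <= 0):
        raise ValueError("SOC and TN must be > 0")
    out = pd.DataFrame(
        {
            "BRC/SOC": 100.0 * residues["BRC"].to_numpy(float) / soc,
            "BRN/TN": 100.0 * residues["BRN"].to_numpy(float) / tn,
            "FRC/SOC": 100.0 * residues["FRC"].to_numpy(float) / soc,
            "FRN/TN": 100.0 * residues["FRN"].to_numpy(float) / tn,
        },
        index=residues.index,
    )
    return out


@dataclass
class LsdResult:
    """One-way ANOVA + Fisher LSD outcome with compact-letter display."""

    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    group_means: pd.Series
    letters: dict[str, str]
    pairwise: pd.DataFrame  # columns: group1, group2, t, p, significant


def _compact_letters(levels: Sequence[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Assign letters so two groups share one iff not significantly different.

    Groups sharing a letter correspond to maximal cliques of the
    non-significance graph; cliques are lettered in order of their
    highest-ranked (first-listed) member so output is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(tuple(p) for p in nonsig_pairs if len(p) == 2)
    order = {lvl: i for i, lvl in enumerate(levels)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: [order[m] for m in c],
    )
    letters: dict[str, str] = {lvl: "" for lvl in levels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for member in clique:
            letters[member] += alphabet[i % len(alphabet)]
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def fisher_lsd(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str] | pd.Series,
    alpha: float = 0.05,
) -> LsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    Pairwise t statistics use the pooled within-group mean square from the
    ANOVA (df = N - k).  Letters are assigned so that groups sharing a
    letter are not significantly different at ``alpha``.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    by = {lvl: y[(g == lvl).to_numpy()] for lvl in levels}
    for lvl, arr in by.items():
        if len(arr) < 2:
            raise ValueError(f"group {lvl!r} has fewer than 2 observations")
    n = len(y)
    k = len(levels)
    grand = y.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in by.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in by.values())
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance in every group; LSD undefined")
    mse = ss_within / df_w
    f = (ss_between / df_b) / mse
    p = float(stats.f.sf(f, df_b, df_w))

    means = pd.Series({lvl: by[lvl].mean() for lvl in levels})
    ordered = sorted(levels, key=lambda l: -means[l])
    rows = []
    nonsig: set[frozenset] = set()
    for a, b in combinations(ordered, 2):
        se = np.sqrt(mse * (1.0 / len(by[a]) + 1.0 / len(by[b])))
        t = (by[a].mean() - by[b].mean()) / se
        pp = float(2.0 * stats.t.sf(abs(t), df_w))
        sig = pp < alpha
        if not sig:
            nonsig.add(frozenset((a, b)))
        rows.append({"group1": a, "group2": b, "t": t, "p": pp, "significant": sig})
    letters = _compact_letters(ordered, nonsig)
    return LsdResult(
        anova_f=float(f),
        anova_p=p,
        df_between=df_b,
        df_within=df_w,
        group_means=means,
        letters=letters,
        pairwise=pd.DataFrame(rows),
    )
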