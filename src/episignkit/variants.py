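"""Rare-variant classification and carrier-level domain burden testing.

Ultrarare variants (minor allele count <= 2 in every reference panel) are
collapsed into protein-truncating (PTV), protein-altering (PAV) and
synonymous (SYN) classes, annotated against a protein domain model
(disulfide-bonded cysteines, EGF-like repeats, ligand-contact residues,
intracellular domains), tiered by in-silico pathogenicity evidence (PP3),
and tested for carrier enrichment in cases versus controls with a
two-sided Fisher exact test and Benjamini-Hochberg adjustment over the
battery of scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import ValidationError

PTV_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_acceptor", "splice_donor"}
)
PAV_CONSEQUENCES = frozenset({"missense", "inframe_indel"})

TIERS = ("neutral", "supporting", "moderate", "strong")

#: Per-tool PP3 evidence-tier thresholds (score >= threshold reaches the
#: tier).  Calibrated cut-offs of this form come from external evidence
#: calibration studies; these defaults are editable configuration, not
#: package-asserted truth.  ``None`` means the tool cannot reach that tier.
DEFAULT_PP3_THRESHOLDS: dict[str, dict[str, float | None]] = {
    "revel": {"supporting": 0.644, "moderate": 0.773, "strong": 0.932},
    "cadd": {"supporting": 25.3, "moderate": 28.1, "strong": None},
    "mpc": {"supporting": 1.36, "moderate": 1.828, "strong": None},
}

SPLICEAI_CUTOFF = 0.5
LIGAND_SITE_FLANK = 5


@dataclass(frozen=True)
class DomainModel:
    """Protein feature annotation used for domain-level burden scenarios.

    ``features`` holds ``(type, start, end)`` intervals (1-based inclusive
    protein coordinates); ``disulfide_residues`` the cysteine positions of
    annotated disulfide pairs; ``ligand_site_residues`` the ligand-contact
    core residues already expanded by +/- ``LIGAND_SITE_FLANK``.
    """

    features: tuple[tuple[str, int, int], ...]
    disulfide_residues: frozenset[int]
    ligand_site_residues: frozenset[int]
    protein_length: int

    def in_feature(self, residue: int, feature_type: str) -> bool:
        return any(
            s <= residue <= e for (t, s, e) in self.features if t == feature_type
        )


def load_domain_model(path: str | Path | None = None) -> DomainModel:
    """Load a domain model from a feature TSV (type/name/start/end).

    With no path, the bundled synthetic emulation of a receptor feature
    table is used.  Rows of type ``disulfide_bond`` contribute both
    endpoint residues to the disulfide set; ``ligand_site`` rows are core
    residues expanded by +/- 5; a ``protein`` row carries the length.
    """
    if path is None:
        ref = resources.files("episignkit.data") / "domain_model_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    feats: list[tuple[str, int, int]] = []
    disulf: set[int] = set()
    ligand_core: set[int] = set()
    length = 0
    for _, row in df.iterrows():
        t, s, e = str(row["type"]), int(row["start"]), int(row["end"])
        if s < 1 or e < s:
            raise ValidationError(f"malformed feature interval {t} [{s}, {e}]")
        if t == "protein":
            length = e
        elif t == "disulfide_bond":
            disulf.update((s, e))
        elif t == "ligand_site":
            ligand_core.update(range(s, e + 1))
        else:
            feats.append((t, s, e))
    ligand = {
        r
        for core in ligand_core
        for r in range(core - LIGAND_SITE_FLANK, core + LIGAND_SITE_FLANK + 1)
    }
    if not length:
        length = max(e for (_, _, e) in feats)
    return DomainModel(
        features=tuple(feats),
        disulfide_residues=frozenset(disulf),
        ligand_site_residues=frozenset(ligand),
        protein_length=length,
    )


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read an annotated variant TSV (one row per variant per carrier)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "cohort", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns: {sorted(missing)}")
    return df


def filter_ultrarare(variants: pd.DataFrame, max_mac: int = 2) -> pd.DataFrame:
    """Retain variants with minor allele count <= ``max_mac`` in every panel.

    Panels are the ``mac_*`` columns; an absent value is treated as 0 with
    a warning (the variant was not seen in that panel).
    """
    mac_cols = [c for c in variants.columns if c.startswith("mac_")]
    if not mac_cols:
        warnings.warn("no mac_* columns present; treating all panels as MAC 0")
        return variants.copy()
    macs = variants[mac_cols]
    if macs.isna().any().any():
        warnings.warn("absent MAC values treated as 0")
        macs = macs.fillna(0)
    if (macs.to_numpy() < 0).any():
        raise ValidationError("negative minor allele count")
    keep = (macs <= max_mac).all(axis=1)
    return variants.loc[keep].copy()


def collapse_class(variants: pd.DataFrame) -> pd.DataFrame:
    """Collapse consequences into PTV / PAV / SYN / other.

    Stop-gain, frameshift and canonical splice-site variants are PTVs;
    missense and in-frame indels are PAVs; synonymous are SYN.  Variants
    with a SpliceAI score >= 0.5 additionally get a ``splice_altering``
    flag regardless of class.
    """
    out = variants.copy()
    cons = out["consequence"].astype(str)
    cls = np.select(
        [cons.isin(PTV_CONSEQUENCES), cons.isin(PAV_CONSEQUENCES), cons == "synonymous"],
        ["PTV", "PAV", "SYN"],
        default="other",
    )
    out["variant_class"] = cls
    spliceai = out["spliceai"] if "spliceai" in out else pd.Series(np.nan, index=out.index)
    out["splice_altering"] = spliceai.fillna(0.0) >= SPLICEAI_CUTOFF
    return out


def _tool_tier(score: float, ladder: Mapping[str, float | None]) -> str:
    tier = "neutral"
    for name in ("supporting", "moderate", "strong"):
        cut = ladder.get(name)
        if cut is not None and score >= cut:
            tier = name
    return tier


def pp3_tier(
    variant: Mapping,
    thresholds: Mapping[str, Mapping[str, float | None]] = DEFAULT_PP3_THRESHOLDS,
) -> str:
    """Combined in-silico evidence tier for a protein-altering variant.

    Each available tool maps to a tier through its threshold ladder; the
    combined call is the modal tier across available tools, with ties
    resolved toward the weaker tier.  A variant with no scores at all is
    ``neutral`` (with a warning).
    """
    per_tool = []
    for tool, ladder in thresholds.items():
        score = variant.get(tool)
        if score is None or (isinstance(score, float) and np.isnan(score)):
            continue
        per_tool.append(_tool_tier(float(score), ladder))
    if not per_tool:
        warnings.warn("no in-silico scores available; PP3 tier set to neutral")
        return "neutral"
    counts = {t: per_tool.count(t) for t in set(per_tool)}
    best = max(counts.values())
    modal = [t for t, c in counts.items() if c == best]
    return min(modal, key=TIERS.index)  # weaker tier wins ties


def add_pp3_tiers(
    variants: pd.DataFrame,
    thresholds: Mapping[str, Mapping[str, float | None]] = DEFAULT_PP3_THRESHOLDS,
) -> pd.DataFrame:
    """Vector wrapper over :func:`pp3_tier`; non-PAV rows get ``pp3 = ''``."""
    out = variants.copy()
    tiers = []
    for _, row in out.iterrows():
        if row.get("variant_class") == "PAV":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tiers.append(pp3_tier(row, thresholds))
        else:
            tiers.append("")
    out["pp3"] = tiers
    return out


def annotate_domain_effects(variants: pd.DataFrame, model: DomainModel) -> pd.DataFrame:
    """Flag protein-level consequences against the domain model.

    Adds boolean columns ``disulfide_disrupted`` (reference cysteine at an
    annotated disulfide position), ``novel_cysteine`` (non-cysteine
    residue mutated to cysteine), ``near_ligand_site``, and one
    ``in_<feature>`` column per feature type.
    """
    out = variants.copy()
    res = pd.to_numeric(out.get("residue_start"), errors="coerce")
    if (res > model.protein_length).any():
        bad = out.loc[res > model.protein_length, "hgvs_p"].tolist()[:3]
        raise ValidationError(f"residue beyond protein length: {bad}")
    is_protein = out["variant_class"].isin(["PAV"]) if "variant_class" in out else res.notna()
    ref = out.get("ref_aa", pd.Series("", index=out.index)).astype(str)
    alt = out.get("alt_aa", pd.Series("", index=out.index)).astype(str)
    disulf = res.isin(sorted(model.disulfide_residues)) & (ref == "C") & is_protein
    out["disulfide_disrupted"] = disulf.fillna(False)
    out["novel_cysteine"] = ((alt == "C") & (ref != "C") & is_protein).fillna(False)
    out["near_ligand_site"] = (
        res.isin(sorted(model.ligand_site_residues)) & is_protein
    ).fillna(False)
    for ftype in sorted({t for (t, _, _) in model.features}):
        ivs = [(s, e) for (t, s, e) in model.features if t == ftype]
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        hit = res.apply(
            lambda r: bool(np.any((starts <= r) & (r <= ends))) if pd.notna(r) else False
        )
        out[f"in_{ftype}"] = hit & is_protein
    return out


@dataclass(frozen=True)
class ScenarioDef:
    """A named carrier scenario: a deterministic predicate over annotated rows."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def qualifying(self, variants: pd.DataFrame) -> pd.Series:
        mask = self.predicate(variants)
        return mask.fillna(False).astype(bool)


def _pav(df: pd.DataFrame) -> pd.Series:
    return df["variant_class"] == "PAV"


def default_scenarios() -> list[ScenarioDef]:
    """The 17-scenario battery: variant classes, in-silico tiers, and
    per-domain PAV burden."""
    return [
        ScenarioDef("PTVs", lambda d: d["variant_class"] == "PTV"),
        ScenarioDef("Disulfide bonds", lambda d: _pav(d) & d["disulfide_disrupted"]),
        ScenarioDef("EGF-like repeats", lambda d: _pav(d) & d["in_egf_repeat"]),
        ScenarioDef("PAVs (PP3str)", lambda d: _pav(d) & (d["pp3"] == "strong")),
        ScenarioDef("PAVs (PP3mod)", lambda d: _pav(d) & (d["pp3"] == "moderate")),
        ScenarioDef("Novel cysteine formation", lambda d: _pav(d) & d["novel_cysteine"]),
        ScenarioDef(
            "EGF-like repeats (excl. Disulfide bonds)",
            lambda d: _pav(d) & d["in_egf_repeat"] & ~d["disulfide_disrupted"],
        ),
        ScenarioDef("RAM", lambda d: _pav(d) & d["in_ram"]),
        ScenarioDef("Ankyrin", lambda d: _pav(d) & d["in_ankyrin"]),
        ScenarioDef("PAVs (PP3sup)", lambda d: _pav(d) & (d["pp3"] == "supporting")),
        ScenarioDef("SYN", lambda d: d["variant_class"] == "SYN"),
        ScenarioDef("TAD", lambda d: _pav(d) & d["in_tad"]),
        ScenarioDef("LNR", lambda d: _pav(d) & d["in_lnr"]),
        ScenarioDef("PEST", lambda d: _pav(d) & d["in_pest"]),
        ScenarioDef("PAVs (neutral or benign in-silico)", lambda d: _pav(d) & (d["pp3"] == "neutral")),
        ScenarioDef("HD", lambda d: _pav(d) & d["in_hd"]),
        ScenarioDef("PSEN", lambda d: _pav(d) & d["in_psen"]),
    ]


def carrier_table(
    variants: pd.DataFrame,
    scenario: ScenarioDef,
    n_cases: int,
    n_controls: int,
) -> tuple[int, int, int, int]:
    """2x2 carrier counts (a, b, c, d) for a scenario.

    A sample is a carrier if it holds at least one qualifying variant;
    each sample counts once.  ``a``/``c`` are case/control carriers,
    ``b``/``d`` the complements.
    """
    mask = scenario.qualifying(variants)
    qual = variants.loc[mask]
    a = qual.loc[qual["cohort"] == "case", "sample_id"].nunique()
    c = qual.loc[qual["cohort"] == "control", "sample_id"].nunique()
    if a > n_cases or c > n_controls:
        raise ValidationError(
            f"{scenario.name}: carrier count exceeds cohort size ({a}/{n_cases}, {c}/{n_controls})"
        )
    return a, n_cases - a, c, n_controls - c


@dataclass
class ContingencyResult:
    """Fisher exact test result for one carrier scenario."""

    scenario: str
    a: int
    b: int
    c: int
    d: int
    or_sample: float  # cross-product ratio ad/bc, inf when bc = 0 and ad > 0
    or_cmle: float  # conditional maximum-likelihood odds ratio
    ci95: tuple[float, float]
    p_raw: float
    p_adj: float | None = None
    or_defined: bool = True


def fisher_enrichment(table: tuple[int, int, int, int], scenario: str = "") -> ContingencyResult:
    """Two-sided Fisher exact test with sample and conditional-MLE odds ratios.

    The two-sided p sums all tables (at fixed margins) whose hypergeometric
    probability does not exceed the observed table's.  The headline odds
    ratio is the sample cross-product ratio ad/bc (infinite when a
    denominator cell is 0); the exact conditional 95% CI accompanies it.
    An all-zero margin yields p = 1 with the odds ratio flagged undefined.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency counts must be non-negative")
    arr = np.array([[a, b], [c, d]])
    if arr.sum() == 0 or arr.sum(axis=0).min() + arr.sum(axis=1).min() == 0:
        pass
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return ContingencyResult(
            scenario, a, b, c, d, float("nan"), float("nan"), (0.0, float("inf")),
            1.0, or_defined=False,
        )
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    if b * c == 0:
        or_sample = float("inf") if a * d > 0 else float("nan")
    else:
        or_sample = (a * d) / (b * c)
    res = _odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    return ContingencyResult(
        scenario, a, b, c, d, or_sample, float(res.statistic),
        (float(ci.low), float(ci.high)), float(p),
    )


def adjust_scenarios(
    results: Sequence[ContingencyResult], n_tests: int | None = None
) -> list[ContingencyResult]:
    """Benjamini-Hochberg adjustment across the scenario battery.

    ``n_tests`` fixes the number of tests m (the battery size) even when
    fewer results are supplied; defaults to the number of results.
    """
    from .diffmeth import bh_adjust

    m = n_tests if n_tests is not None else len(results)
    if len(results) > m:
        raise ValidationError("more results than declared tests")
    p = np.array([r.p_raw for r in results])
    adj = bh_adjust(p, m=m)
    out = []
    for r, pa in zip(results, adj):
        out.append(
            ContingencyResult(
                r.scenario, r.a, r.b, r.c, r.d, r.or_sample, r.or_cmle,
                r.ci95, r.p_raw, float(pa), r.or_defined,
            )
        )
    return out


def run_burden(
    variants: pd.DataFrame,
    model: DomainModel,
    n_cases: int,
    n_controls: int,
    scenarios: Sequence[ScenarioDef] | None = None,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Full burden analysis: ultrarare filter -> classify -> annotate ->
    per-scenario Fisher tests -> BH adjustment.  Returns one row per
    scenario in battery order."""
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    if n_tests is None:
        n_tests = len(scenarios)
    v = filter_ultrarare(variants)
    v = collapse_class(v)
    v = add_pp3_tiers(v)
    v = annotate_domain_effects(v, model)
    results = [
        fisher_enrichment(carrier_table(v, sc, n_cases, n_controls), sc.name)
        for sc in scenarios
    ]
    results = adjust_scenarios(results, n_tests=n_tests)
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "carrier_cases": [r.a for r in results],
            "carrier_controls": [r.c for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "odds_ratio": [r.or_sample for r in results],
            "or_cmle": [r.or_cmle for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "significant": [r.p_adj is not None and r.p_adj < 0.05 for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Published study inputs (printed tables used as fixed inputs)

#: Cohort sizes of the exome case-control study.
STUDY_N_CASES = 3907
STUDY_N_CONTROLS = 5157
STUDY_N_TESTS = 17

#: Printed per-scenario carrier counts (carrier cases, carrier controls)
#: from the case-control enrichment study, in battery order.
STUDY_CARRIER_COUNTS: dict[str, tuple[int, int]] = {
    "PTVs": (17, 1),
    "Disulfide bonds": (10, 1),
    "EGF-like repeats": (17, 5),
    "PAVs (PP3str)": (7, 0),
    "PAVs (PP3mod)": (10, 3),
    "Novel cysteine formation": (4, 0),
    "EGF-like repeats (excl. Disulfide bonds)": (8, 4),
    "RAM": (1, 0),
    "Ankyrin": (2, 1),
    "PAVs (PP3sup)": (3, 2),
    "SYN": (6, 6),
    "TAD": (3, 3),
    "LNR": (2, 2),
    "PEST": (2, 2),
    "PAVs (neutral or benign in-silico)": (9, 12),
    "HD": (0, 1),
    "PSEN": (0, 1),
}

#: Literature-review carrier counts: disulfide-disrupting missense carriers
#: among published syndromic (AOS) vs heart-defect (CHD) cases, and
#: ligand-site-vicinity PAVs in the same groups.
LITERATURE_DISULFIDE = {"AOS": (10, 44), "CHD": (14, 238)}
LITERATURE_LIGAND_SITE = {"AOS": (8, 44), "CHD": (2, 238)}


def study_enrichment() -> pd.DataFrame:
    """Recompute the full enrichment battery from the printed carrier
    counts and cohort sizes (17 Fisher tests + BH adjustment)."""
    results = []
    for name, (a, c) in STUDY_CARRIER_COUNTS.items():
        table = (a, STUDY_N_CASES - a, c, STUDY_N_CONTROLS - c)
        results.append(fisher_enrichment(table, name))
    results = adjust_scenarios(results, n_tests=STUDY_N_TESTS)
    return pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "carrier_cases": [r.a for r in results],
            "carrier_controls": [r.c for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "odds_ratio": [r.or_sample for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
        }
    )


def literature_review_tests() -> dict[str, ContingencyResult]:
    """The two literature-review group comparisons (AOS vs CHD carriers)."""
    out = {}
    for name, table_counts in (
        ("disulfide", LITERATURE_DISULFIDE),
        ("ligand_site", LITERATURE_LIGAND_SITE),
    ):
        (a, n_a) = table_counts["AOS"]
        (c, n_c) = table_counts["CHD"]
        out[name] = fisher_enrichment((a, n_a - a, c, n_c - c), name)
    return out
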