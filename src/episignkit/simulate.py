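"""Synthetic EPIC-like methylation cohorts, reference tracks, and variant cohorts.

The generator produces beta-value matrices with the statistical structure the
downstream analysis assumes: a logit-normal generative model with planted
case/control mean differences on a known probe subset, Dirichlet blood-cell
composition (optionally confounded with case status), batch shifts, and
detection p-value failures.  Because the planted truth is returned alongside
the data, every stage of the discovery pipeline can be scored for sensitivity
and contamination without any external download.

Model per probe p and sample s (logit scale):

    x_ps = mu_p + effect_p * 1[s is case] + b_{p,batch(s)} + w_p . (f_s - f0) + eps_ps
    beta_ps = sigmoid(x_ps)

where ``mu_p`` is a bimodal probe baseline, ``effect_p`` is chosen so that the
case-minus-control mean beta difference at a planted probe is approximately
the configured ``delta`` (sign split hypo/hyper), ``b`` are batch shifts,
``w_p`` are cell-type loadings active on a probe subset, ``f_s`` the sample's
cell-fraction simplex, ``f0`` the expected control composition and ``eps``
Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_qc import BetaMatrix, SampleSheet

_DEF_CONC = (14.0, 5.0, 3.0, 2.0, 1.0)  # granulocyte-dominated blood mix


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Study conditions for a simulated discovery cohort.

    Defaults mirror a small rare-disorder discovery setting: 16 cases
    against 64 matched-eligible controls plus a database background of
    other-disorder and unaffected samples, a planted signature of 300
    probes at a mean beta difference of 0.15.
    """

    n_cases: int = 16
    n_controls: int = 64
    n_database: int = 200
    n_probes: int = 50_000
    n_signature: int = 300
    delta: float = 0.15
    noise_sd: float = 0.3
    n_celltypes: int = 5
    dirichlet_conc_case: Sequence[float] = _DEF_CONC
    dirichlet_conc_control: Sequence[float] = _DEF_CONC
    batch_levels: int = 2
    batch_sd: float = 0.05
    seed: int = 0
    # secondary knobs
    hypo_fraction: float = 0.5  # share of planted probes losing methylation
    detection_fail_rate: float = 0.002
    cell_assoc_fraction: float = 0.2
    cell_effect_sd: float = 3.0
    n_disorders: int = 3  # distinct planted signatures among database samples

    def validate(self) -> None:
        if self.n_signature > self.n_probes:
            raise ConfigurationError("n_signature exceeds n_probes")
        if not (0.0 < self.delta < 1.0):
            raise ConfigurationError("delta must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for name in ("n_cases", "n_controls", "n_probes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_database < 0 or self.n_signature < 0:
            raise ConfigurationError("counts must be non-negative")
        for conc in (self.dirichlet_conc_case, self.dirichlet_conc_control):
            if len(conc) != self.n_celltypes:
                raise ConfigurationError(
                    "Dirichlet concentration length must equal n_celltypes"
                )
        if not (0.0 <= self.hypo_fraction <= 1.0):
            raise ConfigurationError("hypo_fraction must be in [0, 1]")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the planted ground truth."""

    beta: BetaMatrix
    detection_p: pd.DataFrame
    samples: SampleSheet
    truth_probes: set[str]
    truth_cell_fractions: pd.DataFrame
    truth_effects: pd.Series  # signed target beta difference per planted probe
    database_truth: dict[str, set[str]] = field(default_factory=dict)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(1, n + 1)]


def _baseline_betas(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal baseline typical of array methylation: most probes near 0 or 1."""
    comp = rng.choice(3, size=n, p=(0.4, 0.2, 0.4))
    base = np.empty(n)
    base[comp == 0] = rng.beta(2.0, 10.0, size=(comp == 0).sum())
    base[comp == 1] = rng.beta(5.0, 5.0, size=(comp == 1).sum())
    base[comp == 2] = rng.beta(10.0, 2.0, size=(comp == 2).sum())
    return np.clip(base, 0.03, 0.97)


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full case/control/database methylation cohort.

    Identical configs (including seed) give byte-identical outputs.  The
    planted probes have case-minus-control expected mean beta difference
    of approximately ``config.delta`` with the configured hypo/hyper sign
    split; database "disorder" samples carry their own disjoint planted
    signatures against the control baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_probes = config.n_probes
    probe_ids = _probe_ids(n_probes)

    base = _baseline_betas(rng, n_probes)

    # Disjoint planted signatures: main + one per database disorder.
    n_disorders = config.n_disorders if config.n_database > 0 else 0
    total_planted = config.n_signature * (1 + n_disorders)
    if total_planted > n_probes:
        raise ConfigurationError("not enough probes for all planted signatures")
    planted_all = rng.choice(n_probes, size=total_planted, replace=False)
    main_idx = planted_all[: config.n_signature]
    disorder_idx = [
        planted_all[config.n_signature * (k + 1): config.n_signature * (k + 2)]
        for k in range(n_disorders)
    ]

    def plant(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (control baseline, signed beta-scale effect) for planted probes."""
        n = len(idx)
        sign = np.where(rng.random(n) < config.hypo_fraction, -1.0, 1.0)
        lo = np.where(sign > 0, 0.15, 0.15 + config.delta)
        hi = np.where(sign > 0, 0.85 - config.delta, 0.85)
        b0 = rng.uniform(lo, hi)
        return b0, sign * config.delta

    base_main, eff_main = plant(main_idx)
    base[main_idx] = base_main
    effects = np.zeros(n_probes)
    effects[main_idx] = eff_main
    disorder_effects = np.zeros((n_disorders, n_probes))
    for k, idx in enumerate(disorder_idx):
        b0, eff = plant(idx)
        base[idx] = b0
        disorder_effects[k, idx] = eff

    mu = _logit(base)

    # Samples: cases, controls share batches; database gets its own.
    n_cc = config.n_cases + config.n_controls
    n_samples = n_cc + config.n_database
    sample_ids = (
        [f"case_{i:04d}" for i in range(1, config.n_cases + 1)]
        + [f"ctrl_{i:04d}" for i in range(1, config.n_controls + 1)]
        + [f"db_{i:04d}" for i in range(1, config.n_database + 1)]
    )
    group = (
        ["case"] * config.n_cases
        + ["control"] * config.n_controls
        + ["database"] * config.n_database
    )
    case_batches = rng.integers(0, config.batch_levels, size=config.n_cases)
    # Controls mirror case sex/batch cells (matched-control study design):
    # control i takes the covariates of case i mod n_cases, so every case
    # has pool coverage at the matching ratio.
    ctrl_batches = case_batches[np.arange(config.n_controls) % config.n_cases]
    db_batches = rng.integers(0, max(1, config.batch_levels), size=config.n_database)
    batch = [f"B{b + 1}" for b in np.concatenate([case_batches, ctrl_batches])] + [
        f"DB{b + 1}" for b in db_batches
    ]
    n_batch_labels = config.batch_levels + max(1, config.batch_levels)
    batch_codes = np.concatenate([case_batches, ctrl_batches, config.batch_levels + db_batches])
    case_sex = rng.choice(["F", "M"], size=config.n_cases)
    ctrl_sex = case_sex[np.arange(config.n_controls) % config.n_cases]
    sex = np.concatenate(
        [case_sex, ctrl_sex, rng.choice(["F", "M"], size=config.n_database)]
    )
    age = np.round(rng.uniform(0.5, 18.0, size=n_samples), 1)

    # Disorder labels for database samples: half unaffected, rest split.
    disorder_label = ["" for _ in range(n_cc)]
    db_assign = np.full(config.n_database, -1)
    if config.n_database:
        n_unaff = config.n_database // 2
        pool = np.arange(config.n_database)
        rng.shuffle(pool)
        affected = pool[n_unaff:]
        if n_disorders:
            db_assign[affected] = np.arange(len(affected)) % n_disorders
        for i in range(config.n_database):
            disorder_label.append(
                "unaffected" if db_assign[i] < 0 else f"disorder{db_assign[i] + 1}"
            )

    # Cell fractions.
    conc_case = np.asarray(config.dirichlet_conc_case, dtype=float)
    conc_ctrl = np.asarray(config.dirichlet_conc_control, dtype=float)
    fracs = np.vstack(
        [
            rng.dirichlet(conc_case, size=config.n_cases),
            rng.dirichlet(conc_ctrl, size=config.n_controls + config.n_database),
        ]
    )
    f0 = conc_ctrl / conc_ctrl.sum()

    # Probe-level nuisance structure.
    batch_eff = rng.normal(0.0, config.batch_sd, size=(n_probes, n_batch_labels))
    cell_assoc = rng.random(n_probes) < config.cell_assoc_fraction
    loadings = np.zeros((n_probes, config.n_celltypes))
    loadings[cell_assoc] = rng.normal(
        0.0, config.cell_effect_sd, size=(int(cell_assoc.sum()), config.n_celltypes)
    )

    # Assemble logits: probes x samples.
    is_case = np.array([g == "case" for g in group], dtype=float)
    logits = np.tile(mu[:, None], (1, n_samples))
    logits += _logit(np.clip(base + effects, 0.01, 0.99))[:, None] * is_case[None, :]
    logits -= mu[:, None] * is_case[None, :]
    for k in range(n_disorders):
        mask = np.array(
            [disorder_label[s] == f"disorder{k + 1}" for s in range(n_samples)],
            dtype=float,
        )
        shifted = _logit(np.clip(base + disorder_effects[k], 0.01, 0.99))
        logits += (shifted - mu)[:, None] * mask[None, :]
    logits += batch_eff[:, batch_codes]
    logits += loadings @ (fracs - f0).T
    logits += rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))

    beta_values = _sigmoid(logits)

    # Detection failures cluster in a small set of unreliable probes (as on
    # real arrays) rather than spreading uniformly: a probe is "bad" with
    # probability 10x the entry rate and then fails per sample with
    # probability 0.1, keeping the overall entry failure rate at
    # ``detection_fail_rate``.
    detp = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))
    bad_probe = rng.random(n_probes) < min(1.0, 10.0 * config.detection_fail_rate)
    fail = bad_probe[:, None] & (rng.random((n_probes, n_samples)) < 0.1)
    detp[fail] = rng.uniform(0.1, 1.0, size=int(fail.sum()))

    beta_df = pd.DataFrame(beta_values, index=probe_ids, columns=sample_ids)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "sex": sex,
            "age": age,
            "batch": batch,
            "disorder_label": disorder_label,
        }
    )
    cf_cols = {f"cf_{t + 1}": fracs[:, t] for t in range(config.n_celltypes)}
    sheet = pd.concat([sheet, pd.DataFrame(cf_cols)], axis=1)

    truth = {probe_ids[i] for i in main_idx}
    return SimulatedCohort(
        beta=BetaMatrix(beta_df),
        detection_p=detp_df,
        samples=SampleSheet(sheet),
        truth_probes=truth,
        truth_cell_fractions=pd.DataFrame(
            fracs, index=sample_ids, columns=[f"cf_{t + 1}" for t in range(config.n_celltypes)]
        ),
        truth_effects=pd.Series(eff_main, index=[probe_ids[i] for i in main_idx]),
        database_truth={
            f"disorder{k + 1}": {probe_ids[i] for i in disorder_idx[k]}
            for k in range(n_disorders)
        },
    )


# ---------------------------------------------------------------------------
# Reference tracks


def generate_reference_tracks(
    n_islands: int,
    genome_length: int,
    seed: int = 0,
    n_genes: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate CpG-island intervals, gene-part intervals, and probe coordinates.

    Intervals are 0-based half-open on a single synthetic chromosome.
    Islands are spaced at least 9 kb apart so that shore (0-2 kb), shelf
    (2-4 kb) and inter-CGI (open sea) probes all exist; probes are placed
    to cover every annotation class.  Gene models emit promoter (2 kb
    upstream of the TSS, strand-aware), UTR, CDS and intron parts.
    """
    if n_islands < 1:
        raise ConfigurationError("n_islands must be >= 1")
    genome_length = int(genome_length)
    rng = np.random.default_rng(seed)
    max_len, gap = 1500, 9000
    if n_islands * (max_len + gap) + gap > genome_length:
        raise ConfigurationError("genome_length too small to place islands")

    chrom = "chr1"
    islands = []
    pos = gap
    slack = genome_length - gap - n_islands * (max_len + gap)
    extra = rng.multinomial(slack // 100, np.full(n_islands, 1.0 / n_islands)) * 100
    for i in range(n_islands):
        length = int(rng.integers(300, max_len + 1))
        start = pos + int(extra[i])
        islands.append((chrom, start, start + length))
        pos = start + length + gap
    cgi = pd.DataFrame(islands, columns=["chrom", "start", "end"])

    # Probes covering island / shore / shelf / inter-CGI around each island.
    probes = []
    for _, isl in cgi.iterrows():
        s, e = int(isl.start), int(isl.end)
        mid = (s + e) // 2
        probes += [mid, e + int(rng.integers(1, 2000)), e + int(rng.integers(2100, 3900)),
                   e + int(rng.integers(4200, 8000))]
    # plus uniform background probes
    probes += [int(p) for p in rng.integers(0, genome_length, size=4 * n_islands)]
    probes = sorted(set(min(p, genome_length - 1) for p in probes))
    probe_df = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(1, len(probes) + 1)],
            "chrom": chrom,
            "pos": probes,
        }
    )

    # Gene models: anchored near islands (promoters often CGI-associated).
    if n_genes is None:
        n_genes = max(2, n_islands // 2)
    genes = []
    for g in range(n_genes):
        isl = cgi.iloc[g % len(cgi)]
        strand = "+" if rng.random() < 0.5 else "-"
        name, tx = f"GENE{g + 1}", f"TX{g + 1}"
        exon = int(rng.integers(150, 400))
        intron = int(rng.integers(800, 2500))
        utr5, utr3 = int(rng.integers(100, 300)), int(rng.integers(150, 400))
        if strand == "+":
            tss = int(isl.start) + int(rng.integers(0, max(1, int(isl.end - isl.start))))
            parts = [("promoter", tss - 2000, tss), ("five_utr", tss, tss + utr5)]
            cur = tss + utr5
            for k in range(3):
                parts.append(("cds", cur, cur + exon))
                cur += exon
                if k < 2:
                    parts.append(("intron", cur, cur + intron))
                    cur += intron
            parts.append(("three_utr", cur, cur + utr3))
        else:
            tes = int(isl.start) + int(rng.integers(0, max(1, int(isl.end - isl.start))))
            cur = tes
            parts = [("three_utr", cur, cur + utr3)]
            cur += utr3
            for k in range(3):
                parts.append(("cds", cur, cur + exon))
                cur += exon
                if k < 2:
                    parts.append(("intron", cur, cur + intron))
                    cur += intron
            parts.append(("five_utr", cur, cur + utr5))
            cur += utr5
            parts.append(("promoter", cur, cur + 2000))
        for part, s0, e0 in parts:
            genes.append((chrom, max(0, s0), min(genome_length, e0), name, tx, part, strand))
    gene_df = pd.DataFrame(
        genes, columns=["chrom", "start", "end", "gene", "transcript", "part", "strand"]
    )
    return cgi, gene_df, probe_df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED (0-based half-open); gene parts encode
    ``gene|transcript|part|strand`` in the name field."""
    out = df[["chrom", "start", "end"]].copy()
    if "part" in df.columns:
        out["name"] = (
            df["gene"] + "|" + df["transcript"] + "|" + df["part"] + "|" + df["strand"]
        )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED intervals; a 4th ``gene|transcript|part|strand`` field is
    split back into columns when present."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        rows.append(fields)
    n = max(len(r) for r in rows)
    if n >= 4 and "|" in rows[0][3]:
        df = pd.DataFrame(rows).iloc[:, :4]
        df.columns = ["chrom", "start", "end", "name"]
        parts = df["name"].str.split("|", expand=True)
        df[["gene", "transcript", "part", "strand"]] = parts
        df = df.drop(columns="name")
    else:
        df = pd.DataFrame(rows).iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Variant cohorts


def generate_variant_cohort(
    n_cases: int,
    n_controls: int,
    class_rates: Mapping[str, tuple[float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an annotated variant table with planted class-specific burden.

    ``class_rates`` maps a scenario name to ``(case_rate, control_rate)``
    carrier probabilities; realized carrier counts are Binomial(n, rate)
    per cohort.  Each carrier receives one qualifying variant whose
    annotations (consequence, residue, amino acids, in-silico scores,
    minor allele counts) satisfy the named scenario's predicate.
    Recognised scenario names: ``PTV``, ``SYN``, ``disulfide``,
    ``novel_cysteine``, ``egf``, ``pp3_strong``, ``pp3_moderate``,
    ``pp3_supporting``, ``pav_neutral``.
    """
    from .variants import load_domain_model  # deferred: avoids import cycle

    for name, (rc, rn) in class_rates.items():
        if not (0.0 <= rc <= 1.0 and 0.0 <= rn <= 1.0):
            raise ConfigurationError(f"rates for {name!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    model = load_domain_model()
    disulfide = sorted(model.disulfide_residues)
    egf_iv = [(s, e) for (t, s, e) in model.features if t == "egf_repeat"]

    def make_variant(scenario: str) -> dict:
        v: dict = {
            "consequence": "missense",
            "residue_start": int(rng.integers(1, model.protein_length + 1)),
            "ref_aa": "A",
            "alt_aa": "V",
            "cadd": float(rng.uniform(0, 20)),
            "revel": float(rng.uniform(0, 0.4)),
            "mpc": float(rng.uniform(0, 1)),
            "spliceai": float(rng.uniform(0, 0.2)),
        }
        if scenario == "PTV":
            v["consequence"] = str(
                rng.choice(["stop_gained", "frameshift", "splice_acceptor", "splice_donor"])
            )
            v["ref_aa"], v["alt_aa"] = "Q", "*"
        elif scenario == "SYN":
            v["consequence"] = "synonymous"
            v["alt_aa"] = v["ref_aa"]
        elif scenario == "disulfide":
            v["residue_start"] = int(disulfide[int(rng.integers(len(disulfide)))])
            v["ref_aa"], v["alt_aa"] = "C", "Y"
        elif scenario == "novel_cysteine":
            v["ref_aa"], v["alt_aa"] = "R", "C"
        elif scenario == "egf":
            s, e = egf_iv[int(rng.integers(len(egf_iv)))]
            v["residue_start"] = int(rng.integers(s, e + 1))
        elif scenario == "pp3_strong":
            # only the REVEL ladder reaches "strong" under the default
            # thresholds, so strong-evidence variants carry REVEL alone
            v["cadd"], v["revel"], v["mpc"] = np.nan, 0.95, np.nan
        elif scenario == "pp3_moderate":
            v["cadd"], v["revel"], v["mpc"] = 29.0, 0.80, 2.0
        elif scenario == "pp3_supporting":
            v["cadd"], v["revel"], v["mpc"] = 26.0, 0.70, 1.5
        elif scenario == "pav_neutral":
            pass
        else:
            raise ConfigurationError(f"unknown scenario template {scenario!r}")
        v["residue_end"] = v["residue_start"]
        return v

    rows = []
    vid = 0
    for scenario, (rate_case, rate_ctrl) in class_rates.items():
        for cohort, n, rate in (("case", n_cases, rate_case), ("control", n_controls, rate_ctrl)):
            n_carriers = int(rng.binomial(n, rate))
            carriers = rng.choice(n, size=n_carriers, replace=False)
            for c in carriers:
                vid += 1
                v = make_variant(scenario)
                rows.append(
                    {
                        "sample_id": f"{cohort}_{c + 1:05d}",
                        "cohort": cohort,
                        "gene": "GENE_SYNTH",
                        "hgvs_c": f"c.{vid}A>G",
                        "hgvs_p": f"p.({v['ref_aa']}{v['residue_start']}{v['alt_aa']})",
                        "scenario_truth": scenario,
                        "mac_gnomad": int(rng.integers(0, 3)),
                        "mac_internal": int(rng.integers(0, 3)),
                        "mac_ukbb": int(rng.integers(0, 3)),
                        **v,
                    }
                )
    cols = [
        "sample_id", "cohort", "gene", "hgvs_c", "hgvs_p", "consequence",
        "residue_start", "residue_end", "ref_aa", "alt_aa",
        "mac_gnomad", "mac_internal", "mac_ukbb",
        "cadd", "revel", "mpc", "spliceai", "scenario_truth",
    ]
    return pd.DataFrame(rows, columns=cols)
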