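"""End-to-end orchestration: simulate → preprocess → derive → score →
classify → weighted survival → report.

The pipeline mirrors the analysis flow of a biomarker sub-study nested in
an adjuvant trial: QC-filter the expression matrix, derive (or load) the
phospho-JNK signature, median-split the cohort into low/high pJNK groups,
call molecular subtypes and TIME classes, flag immune-related tumors (IM
subtype or TILs > 30%), build the stratified case-cohort sample with
Horvitz–Thompson weights, and fit weighted Cox models with subtype × pJNK
interaction terms per endpoint, BH-adjusting the interaction p values
within each endpoint's family.

Everything is deterministic under ``PipelineConfig.seed``: the simulation,
derivation and sampling stages receive fixed offsets of that one seed, and
the serialized report is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .preprocess import (
    DEFAULT_MIN_MAPPED_READS,
    DEFAULT_MIN_PREVALENCE,
    ExpressionMatrix,
    filter_genes_by_prevalence,
    filter_samples_by_mapped_reads,
    log_normalize,
)
from .sigderive import DerivationConfig, GeneSignature, derive_signature
from .sigscore import dichotomize_by_median, score_samples
from .subtype import SubtypeGeneSets, TimeConfig, assign_subtype, classify_time, compute_subtype_scores
from .survweight import (
    bh_adjust,
    compute_ht_weights,
    interaction_hr_test,
    km_estimate_at,
    weighted_cox_fit,
    weighted_km_by_group,
)
from .synthio import (
    ClinicalCohort,
    LatentPhospho,
    SimulationConfig,
    case_cohort_sample,
    draw_subtype_labels,
    generate_clinical_cohort,
    generate_expression_with_latent,
    generate_subtype_gene_sets,
)

FINAL_SUBTYPES = ("BL", "IM", "M", "LAR", "MSL")
IMMUNE_RULES = ("IM_subtype", "TILs_gt_threshold", "either")


class PipelineError(ValueError):
    """Raised when a pipeline stage contract is violated."""


# ------------------------------------------------------------------- I/O

def read_expression(path, units: str | None = None) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (gene ids in column 1, sample header row).

    Units come from a ``#units=`` pragma on the first line or the *units*
    argument.  Ragged rows, duplicate ids, non-numeric cells and empty
    files are rejected with messages naming the offender.
    """
    return ExpressionMatrix.from_tsv(path, units=units)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name, description, then tab-separated gene ids.

    Order-preserving; duplicate genes within a set are collapsed with a
    warning; a line with fewer than 3 fields is a parse error reported
    with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise PipelineError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate gene(s) in set {name!r} collapsed")
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "jnksig") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ------------------------------------------------------------ definitions

def define_immune_related(
    calls: pd.Series,
    tils_percent: pd.Series | None,
    rule: str = "either",
    threshold: float = 30.0,
) -> pd.Series:
    """Flag immune-related tumors: IM subtype and/or TILs strictly above
    the threshold (default 30%), per the configured rule."""
    if rule not in IMMUNE_RULES:
        raise PipelineError(f"unknown immune-related rule {rule!r}; expected one of {IMMUNE_RULES}")
    im = calls == "IM"
    if rule == "IM_subtype":
        flag = im
    else:
        if tils_percent is None or tils_percent.reindex(calls.index).isna().any():
            raise PipelineError(f"rule {rule!r} needs TILs for every sample")
        tils_high = tils_percent.reindex(calls.index) > threshold
        flag = tils_high if rule == "TILs_gt_threshold" else (im | tils_high)
    flag.name = "immune_related"
    return flag


# ----------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    With ``simulation`` set, inputs are generated; otherwise
    ``expression_path``/``clinical_path``/``gene_sets_path`` (and usually
    ``signature_path``) must point at files.  ``seed`` governs every random
    draw: the simulation, derivation and case-cohort stages run on fixed
    offsets of it.
    """

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    derivation: DerivationConfig = field(default_factory=DerivationConfig)
    expression_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None
    signature_path: str | None = None
    min_mapped_reads: int = DEFAULT_MIN_MAPPED_READS
    min_prevalence: float = DEFAULT_MIN_PREVALENCE
    pseudocount: float = 1.0
    til_threshold: float = 30.0
    immune_rule: str = "either"
    endpoints: tuple[str, ...] = ("DFS", "OS", "DRFI", "BCFI")
    km_horizon_months: float = 60.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.til_threshold < 100:
            raise PipelineError(f"til_threshold must be in (0, 100), got {self.til_threshold}")
        if self.immune_rule not in IMMUNE_RULES:
            raise PipelineError(f"unknown immune_rule {self.immune_rule!r}")
        if self.simulation is None:
            for name in ("expression_path", "clinical_path", "gene_sets_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"non-simulate mode: {name} missing or not found ({p})")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load from YAML or JSON; nested simulation/derivation sections
        become their config dataclasses."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw = {**(raw or {}), **overrides}
        if isinstance(raw.get("simulation"), dict):
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if isinstance(raw.get("derivation"), dict):
            raw["derivation"] = DerivationConfig(**raw["derivation"])
        if isinstance(raw.get("endpoints"), list):
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


# ----------------------------------------------------------------- report

@dataclass
class AnalysisReport:
    """Master report: counts, validation r, call tables, per-endpoint fits
    and interaction q-values, KM summaries, and provenance."""

    data: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(_plain(self.data), sort_keys=True, indent=2, allow_nan=True)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.tsv", sep="\t")


# --------------------------------------------------------------- pipeline

def _simulate_inputs(cfg: PipelineConfig):
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    expr, latent, signal_genes = generate_expression_with_latent(sim)
    labels = draw_subtype_labels(sim)
    clinical = generate_clinical_cohort(sim, latent, labels)
    gene_sets = generate_subtype_gene_sets(sim)
    return sim, expr, latent, signal_genes, clinical, gene_sets


def _load_inputs(cfg: PipelineConfig):
    expr = read_expression(cfg.expression_path, units="raw_counts")
    clinical = ClinicalCohort.from_csv(cfg.clinical_path)
    gene_sets = SubtypeGeneSets.from_gmt(read_gmt(cfg.gene_sets_path))
    latent = None
    if "true_pjnk_latent" in clinical.table.columns:
        s = clinical.table["true_pjnk_latent"]
        latent = LatentPhospho(list(s.index), s.to_numpy())
    return None, expr, latent, None, clinical, gene_sets


def run_full_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Execute all stages and assemble the analysis report.

    Per endpoint, one weighted Cox model is fit per stable subtype with
    the subtype indicator, the pJNK-low indicator, their product, and the
    clinical adjusters (tumor size > 2 cm, nodal involvement, CM arm); the
    Wald interaction p values are BH-adjusted within the endpoint family.
    Fits that are not identifiable on the sampled data (constant
    indicator, too few events, separation) are recorded as skipped.
    """
    stage = "inputs"
    try:
        if cfg.simulation is not None:
            sim, expr, latent, signal_genes, clinical, gene_sets = _simulate_inputs(cfg)
            ratio = sim.case_noncase_ratio
        else:
            sim, expr, latent, signal_genes, clinical, gene_sets = _load_inputs(cfg)
            ratio = 3.0
        if latent is None and cfg.signature_path is None:
            raise PipelineError("no signature_path and no phospho response to derive from")

        stage = "preprocess"
        filtered, excluded_samples = filter_samples_by_mapped_reads(expr, cfg.min_mapped_reads)
        filtered = filter_genes_by_prevalence(filtered, cfg.min_prevalence)
        logm = log_normalize(filtered, cfg.pseudocount)
        kept = logm.sample_ids
        clin = ClinicalCohort(clinical.table.loc[kept])
        if latent is not None:
            lat_series = latent.as_series().loc[kept]
            latent = LatentPhospho(kept, lat_series.to_numpy())

        stage = "derive"
        if cfg.signature_path is not None:
            side = Path(str(cfg.signature_path) + ".json")
            sig = GeneSignature.from_files(cfg.signature_path, side if side.exists() else None)
            derivation_report = {"validation_r": sig.derivation_meta.get("validation_r")}
        else:
            deriv = dataclasses.replace(cfg.derivation, seed=cfg.seed + 1)
            sig, derivation_report = derive_signature(logm, latent, deriv)

        stage = "score"
        scores = score_samples(sig, logm)
        groups = dichotomize_by_median(scores)
        pjnk_low = pd.Series(groups.labels == "low", index=groups.sample_ids, name="pjnk_low")

        stage = "classify"
        sub_scores = compute_subtype_scores(logm, gene_sets)
        calls = assign_subtype(sub_scores)
        imm_set, _ = gene_sets.sets["IM"]
        stro_set, _ = gene_sets.sets["MSL"]
        time_calls = classify_time(
            logm, TimeConfig(immune_genes=list(imm_set), stromal_genes=list(stro_set))
        )
        immune_related = define_immune_related(
            calls.as_series(), clin.table["tils_percent"], cfg.immune_rule, cfg.til_threshold
        )

        stage = "case_cohort"
        ccs = case_cohort_sample(clin, ratio=ratio, seed=cfg.seed + 2)
        weights = compute_ht_weights(ccs)
        inc = list(weights.index)

        stage = "survival"
        adjusters = pd.DataFrame(index=clin.table.index)
        adjusters["size_gt2cm"] = clin.table["tumor_size_category"].isin(["T2", "T3"]).astype(float)
        adjusters["nodal_positive"] = (clin.table["nodal_category"] != "N0").astype(float)
        adjusters["treatment_cm"] = (clin.table["treatment"] == "CM").astype(float)
        call_series = calls.as_series()

        endpoint_results: dict[str, dict] = {}
        for ep in cfg.endpoints:
            t, e = clin.endpoint(ep)
            rows, pvals, fitted = [], [], []
            for s in FINAL_SUBTYPES:
                cov = adjusters.loc[inc].copy()
                cov[f"subtype_{s}"] = (call_series.loc[inc] == s).astype(float)
                cov["pjnk_low"] = pjnk_low.loc[inc].astype(float)
                cov[f"subtype_{s}:pjnk_low"] = cov[f"subtype_{s}"] * cov["pjnk_low"]
                try:
                    fit = weighted_cox_fit(
                        t.loc[inc], e.loc[inc], cov, weights,
                        feature_of_interest=[f"subtype_{s}", f"subtype_{s}:pjnk_low"],
                    )
                    res = interaction_hr_test(fit, f"subtype_{s}", f"subtype_{s}:pjnk_low")
                    if abs(res.coef_interaction) > 10 or res.se_interaction > 10:
                        raise PipelineError(
                            "quasi-separation: interaction coefficient at the likelihood "
                            "boundary (an empty subtype x pJNK-group cell)"
                        )
                    rows.append({
                        "subtype": s,
                        "hr_low": res.hr_stratum,
                        "hr_high": res.hr_reference,
                        "hr_inter": res.hr_inter,
                        "p_inter": res.wald_p,
                        "lr_p": fit.lr_p,
                        "n_events": fit.n_events,
                        "skipped": "",
                    })
                    pvals.append(res.wald_p)
                    fitted.append(len(rows) - 1)
                except Exception as exc:  # not identifiable on this sample
                    rows.append({
                        "subtype": s, "hr_low": np.nan, "hr_high": np.nan,
                        "hr_inter": np.nan, "p_inter": np.nan, "lr_p": np.nan,
                        "n_events": np.nan, "skipped": str(exc),
                    })
            if pvals:
                q = bh_adjust(pvals)
                for ix, qv in zip(fitted, q):
                    rows[ix]["q_inter"] = float(qv)
            for r in rows:
                r.setdefault("q_inter", np.nan)
            table = pd.DataFrame(rows).set_index("subtype")

            curves = weighted_km_by_group(
                t.loc[inc].to_numpy(), e.loc[inc].to_numpy(),
                weights.to_numpy(), pjnk_low.loc[inc].map({True: "low", False: "high"}),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                km_at_horizon = {
                    g: km_estimate_at(c, cfg.km_horizon_months) for g, c in curves.items()
                }
            endpoint_results[ep] = {"interactions": table, "km_at_horizon": km_at_horizon}

        stage = "report"
        counts = {
            "n_input_samples": expr.n_samples,
            "n_excluded_low_reads": len(excluded_samples),
            "n_analyzed": len(kept),
            "n_cases": int(clin.table["bcfi_event"].sum()),
            "n_included_case_cohort": len(inc),
            "subtype_counts": call_series.value_counts().sort_index().to_dict(),
            "time_counts": time_calls.value_counts().sort_index().to_dict(),
            "n_immune_related": int(immune_related.sum()),
            "pjnk_group_sizes": pd.Series(groups.labels).value_counts().sort_index().to_dict(),
        }
        data = {
            "counts": counts,
            "signature": {
                "n_genes": len(sig),
                "genes": list(sig.gene_ids),
                "coefficients": [float(c) for c in sig.coefficients],
                "validation_r": derivation_report.get("validation_r"),
            },
            "endpoints": {
                ep: {
                    "interactions": res["interactions"].reset_index().to_dict(orient="records"),
                    "km_at_horizon_months": cfg.km_horizon_months,
                    "km_at_horizon": res["km_at_horizon"],
                }
                for ep, res in endpoint_results.items()
            },
            "provenance": {
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "package_version": _pkg_version,
            },
        }
        tables = {
            "pjnk_scores": pd.DataFrame(
                {"score": scores.scores, "pjnk_group": groups.labels}, index=scores.sample_ids
            ),
            "subtype_calls": pd.concat([calls.table, sub_scores], axis=1),
            "time_calls": time_calls.to_frame(),
            "immune_related": immune_related.to_frame(),
            "ht_weights": weights.to_frame(),
        }
        for ep, res in endpoint_results.items():
            tables[f"interactions_{ep.lower()}"] = res["interactions"]
        report = AnalysisReport(data, tables)
        if cfg.outdir is not None:
            report.write(cfg.outdir)
            sig.to_files(Path(cfg.outdir) / "signature.tsv", Path(cfg.outdir) / "signature.json")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"pipeline stage {stage!r} failed (config {cfg.config_hash()}): {exc}"
        ) from exc
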