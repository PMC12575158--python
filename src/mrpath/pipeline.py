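"""Batch orchestration: forward screening, reverse MR, mediation, reports.

The study design screens many exposures against one outcome (forward MR),
re-tests flagged pairs with the roles swapped (reverse MR, with a more
lenient instrument threshold because outcome GWAS tend to have few
genome-wide-suggestive hits), and then runs two-step mediation through
candidate mediators for the exposures that survive.

A pair is called *causal* when the conjunction holds: IVW p < alpha, no
Egger-intercept pleiotropy flag, Steiger direction true, and reverse-MR
p >= alpha. Heterogeneity does not veto a pair — it is absorbed by the
random-effects IVW model — but the flag is carried in the report.

By default no multiple-testing correction is applied across exposures
(each pair is tested at alpha, mirroring common screening practice);
``correction="bonferroni"`` or ``"fdr_bh"`` is available and logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MREstimate, all_estimates, egger
from .exceptions import ConfigurationError, MrPathError
from .instruments import ClumpConfig, LdMatrix, select_instruments
from .mediation import BootstrapConfig, MediationEstimate, two_step_mediation
from .sensitivity import SensitivityReport, run_sensitivity
from .sumstats import SnpAssociation, harmonize, read_summary_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Batch settings: input paths, per-direction clumping, decision alpha."""

    exposure_paths: list = field(default_factory=list)
    mediator_paths: list = field(default_factory=list)
    outcome_path: str | None = None
    ld_path: str | None = None
    forward_clump: ClumpConfig = field(default_factory=ClumpConfig)
    mediator_clump: ClumpConfig | None = None  # e.g. 1000 kb window for metabolites
    reverse_clump: ClumpConfig = field(default_factory=lambda: ClumpConfig(p_threshold=5e-5))
    alpha: float = 0.05
    correction: str = "none"  # {none, bonferroni, fdr_bh}
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    output_dir: str = "mrpath_out"
    seed: int = 0
    presso_n_sim: int = 5000

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.correction not in ("none", "bonferroni", "fdr_bh"):
            raise ConfigurationError("correction must be none|bonferroni|fdr_bh")
        if self.correction != "none":
            logger.warning("multiple-testing correction %r enabled (screening default is none)",
                           self.correction)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("forward_clump", "mediator_clump", "reverse_clump"):
            if key in raw and raw[key] is not None:
                sub = dict(raw[key])
                if sub.get("mhc_region") is not None:
                    c, s, e = sub["mhc_region"]
                    sub["mhc_region"] = (str(c), int(s), int(e))
                raw[key] = ClumpConfig(**sub)
        if "bootstrap" in raw and raw["bootstrap"] is not None:
            raw["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise ConfigurationError(f"unknown PipelineConfig keys: {sorted(extra)}")
        return cls(**raw)


@dataclass
class ScreenResult:
    """Everything stored for one (exposure, outcome) pair."""

    exposure: str
    outcome: str
    estimates: list  # list[MREstimate]
    sensitivity: SensitivityReport | None
    stage_counts: dict
    n_snp: int
    estimable: bool
    causal: bool | None = None
    reverse_p: float | None = None
    reverse_estimable: bool | None = None
    reverse_steiger: bool | None = None  # does the reverse analysis's own
    # Steiger test support the outcome -> exposure direction?
    error: str | None = None

    @property
    def ivw_estimate(self) -> MREstimate | None:
        for est in self.estimates:
            if est.method in ("ivw_re", "ivw_fe", "wald_ratio"):
                return est
        return None


def decide_causal(result: ScreenResult, alpha: float = 0.05) -> bool:
    """Codified decision rule: IVW significant, no pleiotropy flag, Steiger
    direction true, and reverse MR null. A pure function of stored fields,
    re-derivable from the report.

    An untestable reverse analysis counts as null. A significant reverse
    association whose own Steiger test points back toward the forward
    direction (``reverse_steiger=False``) is discounted: with a strongly
    causal exposure and a well-powered outcome GWAS, the exposure's
    instruments leak into the reverse instrument set, and Steiger
    filtering is what distinguishes that leakage from genuine reverse
    causation."""
    if not result.estimable or result.ivw_estimate is None:
        return False
    ok = result.ivw_estimate.pval < alpha
    if result.sensitivity is not None:
        ok = ok and not result.sensitivity.pleiotropy_flag
        ok = ok and result.sensitivity.steiger_direction
    if (result.reverse_estimable and result.reverse_p is not None
            and result.reverse_steiger is not False):
        ok = ok and result.reverse_p >= alpha
    return bool(ok)


def screen_pair(exposure: list[SnpAssociation], outcome: list[SnpAssociation],
                exposure_name: str, outcome_name: str,
                clump: ClumpConfig, ld: LdMatrix | None = None, *,
                seed: int, alpha: float = 0.05,
                n_exp: int | None = None, n_out: int | None = None,
                presso_n_sim: int = 5000,
                run_sens: bool = True) -> ScreenResult:
    """Instrument chain -> harmonize -> estimators -> sensitivity for one
    exposure-outcome pair. Failures yield a non-estimable result, never an
    exception, so batch screening is isolated per pair."""
    try:
        selected, counts = select_instruments(exposure, ld, clump)
        if not selected:
            return ScreenResult(exposure=exposure_name, outcome=outcome_name,
                                estimates=[], sensitivity=None, stage_counts=counts,
                                n_snp=0, estimable=False, error="no surviving instruments")
        h = harmonize(selected, outcome)
        counts["harmonized"] = h.n_snp
        ests = all_estimates(h, seed=seed)
        sens = None
        if run_sens and h.n_snp >= 3:
            n_e = n_exp or int(np.median([s.n for s in selected]))
            n_o = n_out or int(np.median([s.n for s in outcome]))
            sens = run_sensitivity(h, ests[0], egger(h), n_exp=n_e, n_out=n_o,
                                   seed=seed + 7, alpha=alpha, presso_n_sim=presso_n_sim)
        return ScreenResult(exposure=exposure_name, outcome=outcome_name,
                            estimates=ests, sensitivity=sens, stage_counts=counts,
                            n_snp=h.n_snp, estimable=True)
    except MrPathError as exc:
        logger.warning("pair (%s, %s) not estimable: %s", exposure_name, outcome_name, exc)
        return ScreenResult(exposure=exposure_name, outcome=outcome_name,
                            estimates=[], sensitivity=None, stage_counts={},
                            n_snp=0, estimable=False, error=str(exc))


def _adjusted_alpha(cfg: PipelineConfig, n_tests: int) -> float:
    if cfg.correction == "bonferroni" and n_tests > 0:
        return cfg.alpha / n_tests
    return cfg.alpha


def run_forward_screen(cfg: PipelineConfig,
                       exposures: dict[str, list] | None = None,
                       outcome: list | None = None,
                       ld: LdMatrix | None = None) -> list[ScreenResult]:
    """Screen every exposure against the outcome.

    ``exposures``/``outcome``/``ld`` may be passed in-memory; otherwise
    they are read from the configured paths. Deterministic given the seed.
    """
    if exposures is None:
        exposures = {Path(p).stem: read_summary_table(p) for p in cfg.exposure_paths}
    if outcome is None:
        if cfg.outcome_path is None:
            raise ConfigurationError("no outcome provided")
        outcome = read_summary_table(cfg.outcome_path)
    if ld is None and cfg.ld_path:
        ld = LdMatrix.from_pairs_tsv(cfg.ld_path)
    alpha = _adjusted_alpha(cfg, len(exposures))
    results = []
    for i, (name, stats) in enumerate(sorted(exposures.items())):
        res = screen_pair(stats, outcome, name, "outcome", cfg.forward_clump, ld,
                          seed=cfg.seed + 1000 * i, alpha=alpha,
                          presso_n_sim=cfg.presso_n_sim)
        res.causal = decide_causal(res, alpha)
        results.append(res)
    if cfg.correction == "fdr_bh":
        _apply_fdr(results, cfg.alpha)
    return results


def _apply_fdr(results: list[ScreenResult], alpha: float) -> None:
    est = [r for r in results if r.estimable and r.ivw_estimate is not None]
    if not est:
        return
    pvals = np.array([r.ivw_estimate.pval for r in est])
    order = np.argsort(pvals)
    m = len(pvals)
    passed = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            max_k = rank
    for rank, idx in enumerate(order, start=1):
        passed[idx] = rank <= max_k
    for r, ok in zip(est, passed):
        r.causal = bool(r.causal and ok)


def run_reverse(cfg: PipelineConfig, pairs: list[ScreenResult],
                exposures: dict[str, list] | None = None,
                outcome: list | None = None,
                ld: LdMatrix | None = None) -> dict[str, ScreenResult]:
    """Reverse MR for flagged pairs: the outcome becomes the exposure
    (instruments selected at the reverse threshold, default p < 5e-5) and
    each flagged exposure trait becomes the outcome. Updates each pair's
    ``reverse_p`` and re-derives its causal flag."""
    if exposures is None:
        exposures = {Path(p).stem: read_summary_table(p) for p in cfg.exposure_paths}
    if outcome is None:
        if cfg.outcome_path is None:
            raise ConfigurationError("no outcome provided")
        outcome = read_summary_table(cfg.outcome_path)
    if ld is None and cfg.ld_path:
        ld = LdMatrix.from_pairs_tsv(cfg.ld_path)
    reverse_results: dict[str, ScreenResult] = {}
    for i, res in enumerate(pairs):
        if res.exposure not in exposures:
            continue
        rev = screen_pair(outcome, exposures[res.exposure], "outcome", res.exposure,
                          cfg.reverse_clump, ld, seed=cfg.seed + 500_000 + 1000 * i,
                          alpha=cfg.alpha, presso_n_sim=cfg.presso_n_sim)
        reverse_results[res.exposure] = rev
        res.reverse_estimable = rev.estimable
        res.reverse_p = rev.ivw_estimate.pval if rev.estimable else None
        res.reverse_steiger = (rev.sensitivity.steiger_direction
                               if rev.sensitivity is not None else None)
        res.causal = decide_causal(res, cfg.alpha)
    return reverse_results


def run_mediation_pipeline(cfg: PipelineConfig,
                           causal_exposures: list[str],
                           exposures: dict[str, list],
                           mediators: dict[str, list],
                           outcome: list,
                           ld: LdMatrix | None = None) -> list[dict]:
    """Two-step mediation for every (causal exposure, screened mediator)
    path. Mediators are first screened against the outcome at alpha; for
    surviving mediators the full decomposition is estimated. Per-path
    failures are isolated."""
    med_clump = cfg.mediator_clump or cfg.forward_clump
    paths = []
    # screen mediators against the outcome once
    med_screen: dict[str, ScreenResult] = {}
    for i, (mname, mstats) in enumerate(sorted(mediators.items())):
        med_screen[mname] = screen_pair(
            mstats, outcome, mname, "outcome", med_clump, ld,
            seed=cfg.seed + 900_000 + 1000 * i, alpha=cfg.alpha,
            presso_n_sim=cfg.presso_n_sim, run_sens=False)
    for ename in causal_exposures:
        for mname, mres in sorted(med_screen.items()):
            if not (mres.estimable and mres.ivw_estimate.pval < cfg.alpha):
                continue
            try:
                est = _mediation_path(cfg, exposures[ename], mediators[mname],
                                      outcome, ld)
            except MrPathError as exc:
                logger.warning("mediation path %s -> %s failed: %s", ename, mname, exc)
                paths.append({"exposure": ename, "mediator": mname,
                              "outcome": "outcome", "error": str(exc)})
                continue
            row = {"exposure": ename, "mediator": mname, "outcome": "outcome",
                   "estimate": est}
            paths.append(row)
    return paths


def _mediation_path(cfg: PipelineConfig, exposure, mediator, outcome, ld) -> MediationEstimate:
    exp_sel, _ = select_instruments(exposure, ld, cfg.forward_clump)
    med_clump = cfg.mediator_clump or cfg.forward_clump
    med_sel, _ = select_instruments(mediator, ld, med_clump)
    # a mediator instrument that is also an exposure instrument acts on the
    # outcome through the exposure too, biasing beta2; exclude the overlap
    exp_ids = {s.snp_id for s in exp_sel}
    med_sel = [s for s in med_sel if s.snp_id not in exp_ids]
    h_exp_med = harmonize(exp_sel, mediator)
    h_med_out = harmonize(med_sel, outcome)
    h_exp_out = harmonize(exp_sel, outcome)
    return two_step_mediation(h_exp_med, h_med_out, h_exp_out,
                              cfg=cfg.bootstrap, gate_alpha=cfg.alpha)


def format_or_ci(beta: float, se: float) -> str:
    """Render an effect as ``"OR (low-high)"`` with an en dash, e.g.
    beta=2.1306, se=0.7986 -> ``"8.42 (1.76–40.28)"``."""
    from .estimators import to_odds_ratio

    or_v, lo, hi = to_odds_ratio(beta, se)
    return f"{or_v:.2f} ({lo:.2f}–{hi:.2f})"


def _estimate_row(pair: ScreenResult, est: MREstimate) -> dict:
    return {
        "exposure": pair.exposure, "outcome": pair.outcome,
        "method": est.method, "n_snp": est.n_snp,
        "beta": est.beta, "se": est.se,
        "OR": est.or_value, "OR_low": est.or_low, "OR_high": est.or_high,
        "OR_CI": format_or_ci(est.beta, est.se),
        "pval": est.pval,
    }


def render_report(results: list[ScreenResult], output_dir,
                  mediation_paths: list[dict] | None = None,
                  style: str = "forest_tsv") -> dict[str, Path]:
    """Write the audit outputs: a tidy forest TSV (one row per pair and
    method), a sensitivity TSV, a mediation TSV when paths were run, and a
    machine-readable JSON with everything. Column order and JSON key order
    are stable, so identical inputs give byte-identical files."""
    if style not in ("forest_tsv", "json"):
        raise ValueError("style must be forest_tsv|json")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = [_estimate_row(r, est) for r in results for est in r.estimates]
    forest = out / "forest.tsv"
    pd.DataFrame(rows, columns=["exposure", "outcome", "method", "n_snp", "beta",
                                "se", "OR", "OR_low", "OR_high", "OR_CI", "pval"]
                 ).to_csv(forest, sep="\t", index=False)
    written["forest"] = forest

    sens_rows = []
    for r in results:
        if r.sensitivity is not None:
            row = r.sensitivity.to_frame().iloc[0].to_dict()
            row = {"exposure": r.exposure, "outcome": r.outcome, **row}
            sens_rows.append(row)
    sens = out / "sensitivity.tsv"
    pd.DataFrame(sens_rows).to_csv(sens, sep="\t", index=False)
    written["sensitivity"] = sens

    if mediation_paths:
        med_rows = []
        for p in mediation_paths:
            est = p.get("estimate")
            row = {"exposure": p["exposure"], "mediator": p["mediator"],
                   "outcome": p["outcome"]}
            if est is None:
                row["error"] = p.get("error", "")
            else:
                row.update({
                    "beta1": est.beta1, "se1": est.se1,
                    "beta2": est.beta2, "se2": est.se2,
                    "indirect": est.indirect,
                    "indirect_ci_low": est.indirect_ci_low,
                    "indirect_ci_high": est.indirect_ci_high,
                    "total": est.total, "total_se": est.total_se,
                    "proportion": est.proportion,
                    "consistent_signs": est.consistent_signs,
                    "gate_passed": est.gate_passed, "gate_p": est.gate_p,
                })
            med_rows.append(row)
        med = out / "mediation.tsv"
        pd.DataFrame(med_rows).to_csv(med, sep="\t", index=False)
        written["mediation"] = med

    payload = {
        "pairs": [
            {
                "exposure": r.exposure, "outcome": r.outcome,
                "estimable": r.estimable, "causal": r.causal,
                "n_snp": r.n_snp, "stage_counts": r.stage_counts,
                "reverse_p": r.reverse_p, "reverse_steiger": r.reverse_steiger,
                "error": r.error,
                "estimates": [dataclasses.asdict(e) for e in r.estimates],
                "sensitivity": (None if r.sensitivity is None
                                else json.loads(r.sensitivity.to_frame().iloc[0].to_json())),
            }
            for r in results
        ],
    }
    js = out / "report.json"
    js.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written["json"] = js
    return written
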