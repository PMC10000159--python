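"""End-to-end orchestration: simulate/load -> extract -> fit -> score ->
test -> report.

A run either loads the four input files (event log, sociomatrix,
questionnaire responses, optional chain/ethogram configs) or generates them
from a :class:`~ethochain.simulate.SimulationConfig`. Stages run in a fixed
order and any failure aborts with the stage named. The report carries, per
initial behaviour, the success-score summary (mean +/- sd across sessions)
and the steady-state (success, fail) projection; the omnibus and pairwise
tests across initial behaviours; David's Scores; personality factor means;
and the correlation of factors and dominance with novel-object frequency.
Reports are deterministic: the same inputs and seed give byte-identical
output files (the provenance block contains a config hash and the seed, no
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chains import ChainDefinition, extract_chains, frequency_table, load_chain_definition_file
from .dominance import DavidsScores, Sociomatrix, davids_score, rank_by_ds, read_sociomatrix, write_sociomatrix
from .errors import EthochainError
from .ethogram import Ethogram, load_default_ethogram, load_ethogram_file
from .event_io import EventLog, read_event_log, write_event_log
from .markov import fit_models, steady_state, success_scores
from .personality import (DEFAULT_FACTORS, build_profiles, factor_summary, read_responses,
                          write_responses)
from .simulate import (SimulationConfig, simulate_event_log, simulate_questionnaires,
                       simulate_sociomatrix)
from .stats import correlation_matrix, dunn_pairwise, kruskal_wallis, linear_regression

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs of one pipeline run: either file paths or a simulation config."""

    events_path: str | None = None
    sociomatrix_path: str | None = None
    responses_path: str | None = None
    chain_path: str | None = None
    ethogram_path: str | None = None
    simulation: SimulationConfig | None = None
    outdir: str | Path = "ethochain_out"
    seed: int = 0
    report_precision: int = 2

    def __post_init__(self) -> None:
        has_paths = self.events_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise EthochainError(
                "exactly one of events_path or a simulation config must be supplied")


@dataclass
class RunReport:
    """All computed sections of one run, serialisable to JSON and text."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"provenance": self.provenance, **self.sections},
                          indent=2, sort_keys=True, allow_nan=True)

    def to_text(self, precision: int = 2) -> str:
        p = precision
        lines = ["ethochain run report", "====================", ""]
        mk = self.sections.get("markov", {})
        if mk:
            lines += ["Initial state and success score (mean +/- SD across sessions)"]
            for beh, d in mk.items():
                m = d["success_score_mean"]
                ms = "n/a" if m is None else f"{m:.{p}f} +/- {d['success_score_sd']:.{p}f}"
                lines += [f"  {beh:10s} score {ms}   steady-state [success, fail] = "
                          f"[{d['steady_state_success']:.{p}f}, {d['steady_state_fail']:.{p}f}] "
                          f"(converged at step {d['converged_at_step']}, n={d['n_chains']} chains)"]
            lines += [""]
        tests = self.sections.get("tests", {})
        if "kruskal_wallis" in tests:
            kw = tests["kruskal_wallis"]
            lines += [f"Kruskal-Wallis across initial behaviours: H = {kw['H']:.{p}f}, "
                      f"df = {kw['df']}, p = {kw['p']:.3f}"]
            for d in tests.get("dunn", []):
                lines += [f"  Dunn {d['pair'][0]} vs {d['pair'][1]}: z = {d['z']:.{p}f}, "
                          f"p = {d['p']:.3f}, Bonferroni p = {d['p_adjusted']:.3f}"]
            lines += [""]
        ds = self.sections.get("dominance", {})
        if ds:
            lines += ["David's Scores (descending)"]
            for ind in ds["ranking"]:
                lines += [f"  {ind:8s} DS = {ds['scores'][ind]:+.{p}f}"]
            lines += [""]
        pf = self.sections.get("personality", {})
        if pf:
            lines += ["Personality factor scores (mean +/- SD, percent)"]
            for name, d in pf.items():
                lines += [f"  {name:20s} {d['mean']:.{p}f} +/- {d['sd']:.{p}f}"]
            lines += [""]
        corr = self.sections.get("correlations", {})
        if corr:
            lines += ["Correlation with novel-object interaction frequency"]
            for var, d in corr.get("with_nobj", {}).items():
                r = d["r"]
                rtxt = "n/a" if r is None or (isinstance(r, float) and math.isnan(r)) \
                    else f"r = {r:+.{p}f}, p = {d['p']:.3f}"
                lines += [f"  {var:20s} {rtxt}"]
            reg = corr.get("regression_curiosity_nobj")
            if reg:
                lines += ["", f"Regression novel-object frequency ~ curiosity: "
                          f"R^2 = {reg['r_squared']:.{p}f}, df = {reg['df']}, "
                          f"p = {reg['p']:.3f}"]
            lines += [""]
        lines += [f"seed: {self.provenance.get('seed')}  config: "
                  f"{self.provenance.get('config_hash')}  version: "
                  f"{self.provenance.get('version')}"]
        return "\n".join(lines) + "\n"


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; artifacts are written to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "inputs"
        eth = load_ethogram_file(cfg.ethogram_path) if cfg.ethogram_path else load_default_ethogram()
        chain_def = (load_chain_definition_file(cfg.chain_path) if cfg.chain_path
                     else ChainDefinition())
        socio: Sociomatrix | None = None
        responses = None
        if cfg.simulation is not None:
            stage = "simulate"
            sim = cfg.simulation
            log, _truth = simulate_event_log(sim, chain_def, seed=cfg.seed)
            socio, _ = simulate_sociomatrix(sim, seed=cfg.seed)
            responses, _ = simulate_questionnaires(sim, seed=cfg.seed)
            write_event_log(log, outdir / "events.csv")
            write_sociomatrix(socio, outdir / "sociomatrix.csv")
            write_responses(responses, outdir / "questionnaire.csv")
            factors = list(sim.factors)
        else:
            stage = "load"
            log = read_event_log(cfg.events_path)
            if cfg.sociomatrix_path:
                socio = read_sociomatrix(cfg.sociomatrix_path)
            if cfg.responses_path:
                responses = read_responses(cfg.responses_path)
            factors = list(DEFAULT_FACTORS)
        unknown = [c for c in chain_def.initial_behaviours if c not in eth]
        if unknown:
            logger.warning("initial behaviours not in ethogram: %s", unknown)

        stage = "extract"
        chains = extract_chains(log, chain_def)
        _write_chains_csv(chains, outdir / "chains.csv")
        logger.info("extracted %d chains from %d events", len(chains), len(log))

        stage = "markov"
        k = chain_def.n_states
        summaries = success_scores(chains, k)
        models = fit_models(chains, k)
        mk = {}
        for beh in sorted(summaries):
            s = summaries[beh]
            v, step = steady_state(models[beh])
            succ, fail = v.projection(models[beh])
            mk[beh] = {
                "success_score_mean": s.mean, "success_score_sd": s.sd,
                "per_session_scores": s.per_block_scores,
                "steady_state_success": succ, "steady_state_fail": fail,
                "converged_at_step": step, "n_chains": s.n_chains,
                "transition_probabilities": models[beh].probs.tolist(),
                "state_labels": models[beh].labels,
            }
        report.sections["markov"] = mk
        if not chains:
            report.sections["markov"] = {}
            report.sections["empty_chains"] = True

        stage = "stats"
        tests = {}
        groups = {beh: summaries[beh].per_block_scores for beh in sorted(summaries)
                  if summaries[beh].per_block_scores}
        if len(groups) >= 2 and sum(len(g) for g in groups.values()) >= 3:
            kw = kruskal_wallis(*groups.values())
            tests["kruskal_wallis"] = {"H": kw.statistic, "df": kw.df, "p": kw.p_value}
            tests["dunn"] = [
                {"pair": list(d.groups), "z": d.statistic, "p": d.p_value,
                 "p_adjusted": d.adjusted_p}
                for d in dunn_pairwise(groups, adjust="bonferroni")
            ]
        report.sections["tests"] = tests

        stage = "dominance"
        ds: DavidsScores | None = None
        if socio is not None:
            ds = davids_score(socio)
            report.sections["dominance"] = {
                "scores": ds.as_dict(), "ranking": rank_by_ds(ds),
                "unobserved_dyads": [list(t) for t in ds.unobserved_dyads],
            }

        stage = "personality"
        profiles = []
        if responses:
            profiles = build_profiles(responses, factors, ds)
            report.sections["personality"] = {
                name: {"mean": m, "sd": sd}
                for name, (m, sd) in factor_summary(profiles).items()
            }

        stage = "correlations"
        if profiles:
            nobj = frequency_table(log, "Nobj")
            table, names = _profile_table(profiles, nobj)
            corr_section = {}
            if table.shape[0] >= 3 and table.shape[1] >= 2:
                cm = correlation_matrix(table, names)
                corr_section["matrix"] = {
                    "variables": cm.variables,
                    "r": _nan_to_none(cm.r), "p": _nan_to_none(cm.p),
                }
                j = names.index("nobj_frequency")
                corr_section["with_nobj"] = {
                    v: {"r": _nan_to_none(cm.r[i, j]), "p": _nan_to_none(cm.p[i, j])}
                    for i, v in enumerate(names) if v != "nobj_frequency"
                }
                cur = "curiosity/openness"
                if cur in names:
                    i = names.index(cur)
                    x, y = table[:, i], table[:, j]
                    if len(x) >= 3 and not np.all(x == x[0]):
                        fit = linear_regression(x, y)
                        corr_section["regression_curiosity_nobj"] = {
                            "slope": fit.slope, "intercept": fit.intercept,
                            "r_squared": fit.r_squared,
                            "adjusted_r_squared": fit.adjusted_r_squared,
                            "df": fit.df, "p": fit.p_value,
                        }
            report.sections["correlations"] = corr_section

        stage = "report"
        report.sections = _round_floats(report.sections)
        report.provenance = {
            "seed": cfg.seed,
            "version": __version__,
            "config_hash": _config_hash(cfg),
        }
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
        (outdir / "report.txt").write_text(report.to_text(cfg.report_precision), encoding="utf-8")
        logger.info("run finished in %.2f s; artifacts in %s", time.perf_counter() - t0, outdir)
        return report
    except EthochainError:
        raise
    except Exception as exc:
        raise EthochainError(f"stage {stage!r} failed: {exc}") from exc


def _write_chains_csv(chains, path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["session_id", "initial_behaviour", "initial_actor", "start_time_s",
                    "furthest_state_index", "completed", "completion_fraction", "transitions"])
        for ch in chains:
            w.writerow([ch.session_id, ch.initial_behaviour, ch.initial_actor,
                        format(ch.start_time_s, ".3f"), ch.furthest_state_index,
                        int(ch.completed), format(ch.completion_fraction, ".4f"),
                        ";".join(f"{i}>{j}@{g:.3f}" for i, j, g in ch.transitions)])


def _profile_table(profiles, nobj_counts) -> tuple[np.ndarray, list[str]]:
    factor_names = sorted({n for p in profiles for n in p.scores})
    names = factor_names + ["davids_score", "nobj_frequency"]
    rows = []
    for p in sorted(profiles, key=lambda q: q.individual_id):
        row = [p.scores.get(n, np.nan) for n in factor_names]
        row.append(np.nan if p.davids_score is None else p.davids_score)
        row.append(nobj_counts.get(p.individual_id, 0))
        rows.append(row)
    return np.array(rows, dtype=float), names


def _nan_to_none(x):
    if isinstance(x, np.ndarray):
        return [_nan_to_none(v) for v in x.tolist()]
    if isinstance(x, list):
        return [_nan_to_none(v) for v in x]
    return None if (isinstance(x, float) and math.isnan(x)) else float(x)


def _config_hash(cfg: RunConfig) -> str:
    blob = repr((cfg.events_path, cfg.sociomatrix_path, cfg.responses_path, cfg.chain_path,
                 cfg.ethogram_path, cfg.simulation, cfg.seed, cfg.report_precision))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
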