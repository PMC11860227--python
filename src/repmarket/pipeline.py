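"""End-to-end synthetic experiment: simulate -> trade -> select -> replicate
-> indicators -> evaluate.

The single entry point :func:`run_experiment` expands one global seed
into per-stage substreams (so each stage is rerunnable in isolation),
persists every intermediate table when an output directory is given,
and returns an :class:`ExperimentReport` whose aggregates are all
recomputable from the per-study tables it carries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import evaluation as ev
from .effect_size import InvalidSummaryError, TestSummary, UnsupportedFamilyError
from .indicators import IndicatorReport, StudyPair, indicator_battery, significance_criterion
from .market import SelectionOutcome, select_studies, settle_market
from .synth import (
    GeneratorConfig,
    SyntheticStudy,
    generate_study_population,
    simulate_forecasters,
    simulate_replication,
    simulate_trading,
)

__all__ = [
    "ExperimentReport",
    "run_experiment",
    "read_study_table",
    "pairs_from_table",
    "write_study_table",
    "write_report",
    "evaluate_forecasts",
]

STUDY_COLUMNS = [
    "study_id",
    "role",
    "family",
    "statistic",
    "df",
    "n1",
    "n2",
    "p_two_sided",
    "same_direction",
]


@dataclass
class ExperimentReport:
    """Selection, per-study indicators and aggregate evaluation metrics."""

    selection: SelectionOutcome
    final_prices: pd.Series
    survey_means: pd.Series
    indicator_table: pd.DataFrame
    aggregates: Dict[str, object]
    payouts: Dict[str, float]
    metadata: Dict[str, object]

    def to_dict(self) -> Dict[str, object]:
        return {
            "selection": {
                "top_ids": list(self.selection.top_ids),
                "bottom_ids": list(self.selection.bottom_ids),
                "random_ids": list(self.selection.random_ids),
                "unselected_ids": list(self.selection.unselected_ids),
                "payout_per_share": dict(self.selection.payout_per_share),
            },
            "aggregates": self.aggregates,
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# study-table I/O


def _parse_row(row: pd.Series, line_no: int) -> TestSummary:
    def opt_float(v):
        return None if pd.isna(v) or v == "" else float(v)

    def opt_int(v):
        return None if pd.isna(v) or v == "" else int(v)

    def opt_bool(v):
        if pd.isna(v) or v == "":
            return None
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in ("1", "true", "yes")

    try:
        return TestSummary(
            study_id=str(row["study_id"]),
            role=str(row["role"]),
            family=str(row["family"]),
            statistic=float(row["statistic"]),
            df=opt_float(row.get("df")),
            n1=int(row["n1"]),
            n2=opt_int(row.get("n2")),
            p_two_sided=float(row["p_two_sided"]),
            same_direction=opt_bool(row.get("same_direction")),
        )
    except (InvalidSummaryError, UnsupportedFamilyError, KeyError, ValueError) as exc:
        raise ValueError(f"study table line {line_no}: {exc}") from exc


def read_study_table(path) -> List[TestSummary]:
    """Read a delimited study table; malformed rows report line numbers."""
    frame = pd.read_csv(path)
    missing = [c for c in ("study_id", "role", "family", "statistic", "n1", "p_two_sided")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    return [_parse_row(row, i + 2) for i, (_, row) in enumerate(frame.iterrows())]


def pairs_from_table(summaries: Sequence[TestSummary]) -> List[StudyPair]:
    """Pair originals with replications by study id."""
    originals = {s.study_id: s for s in summaries if s.role == "original"}
    pairs = []
    for s in summaries:
        if s.role == "replication":
            if s.study_id not in originals:
                raise ValueError(f"replication {s.study_id!r} has no original row")
            pairs.append(StudyPair.from_summaries(originals[s.study_id], s))
    return pairs


def write_study_table(summaries: Sequence[TestSummary], path) -> None:
    rows = []
    for s in summaries:
        rows.append(
            {
                "study_id": s.study_id,
                "role": s.role,
                "family": s.family,
                "statistic": s.statistic,
                "df": s.df,
                "n1": s.n1,
                "n2": s.n2,
                "p_two_sided": s.p_two_sided,
                "same_direction": s.same_direction,
            }
        )
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)


def indicator_frame(reports: Sequence[IndicatorReport]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in reports]).set_index("study_id")


# ---------------------------------------------------------------------------
# aggregate evaluation


def evaluate_forecasts(
    prices: Mapping[str, float],
    survey: Mapping[str, float],
    outcomes: Mapping[str, bool],
) -> Dict[str, object]:
    """Forecast-accuracy statistics for the replicated subset.

    ``outcomes`` covers only replicated studies; prices and survey
    beliefs cover the full pool (their correlation uses all of it).
    """
    ids = sorted(outcomes)
    p = np.array([prices[i] for i in ids])
    s = np.array([survey[i] for i in ids])
    y = np.array([bool(outcomes[i]) for i in ids])

    out: Dict[str, object] = {}
    if 0 < y.sum() < len(y):
        pb = ev.point_biserial(p, y)
        out["point_biserial_market"] = {"r": pb.r, "t": pb.t_stat, "p": pb.p, "ci": pb.ci}
        pbs = ev.point_biserial(s, y)
        out["point_biserial_survey"] = {"r": pbs.r, "t": pbs.t_stat, "p": pbs.p, "ci": pbs.ci}
    all_ids = sorted(prices)
    pr = ev.pearson_with_test([prices[i] for i in all_ids], [survey[i] for i in all_ids])
    out["pearson_market_vs_survey"] = {"r": pr.r, "t": pr.t_stat, "p": pr.p, "ci": pr.ci}
    mae_m, brier_m = ev.forecast_scores(p, y)
    mae_s, brier_s = ev.forecast_scores(s, y)
    out["market_scores"] = {"mean_abs_error": mae_m, "mean_brier": brier_m}
    out["survey_scores"] = {"mean_abs_error": mae_s, "mean_brier": brier_s}
    return out


def _aggregate(
    pairs: Sequence[StudyPair],
    reports: Sequence[IndicatorReport],
    selection: SelectionOutcome,
    prices: Mapping[str, float],
    survey: Mapping[str, float],
) -> Dict[str, object]:
    table = indicator_frame(reports)
    outcomes = {r.study_id: bool(r.sig_replicated) for r in reports}
    n = len(reports)

    def rate_with_ci(ids: Sequence[str]) -> Dict[str, object]:
        k = sum(outcomes[i] for i in ids)
        lo, hi = ev.clopper_pearson(k, len(ids))
        return {"k": int(k), "n": len(ids), "rate": k / len(ids), "ci": (lo, hi)}

    d_o = np.array([p.d_original.d for p in pairs])
    d_r = np.array([p.d_replication.d for p in pairs])
    ratio = table["relative_es"].to_numpy()

    agg: Dict[str, object] = {
        "replication_rate": rate_with_ci(list(outcomes)),
        "replication_rate_top": rate_with_ci(list(selection.top_ids)),
        "replication_rate_bottom": rate_with_ci(list(selection.bottom_ids)),
        "mean_d_original": float(d_o.mean()),
        "mean_d_replication": float(d_r.mean()),
        "relative_es_ratio_of_means": float(d_r.mean() / d_o.mean()),
        "relative_es_mean_of_ratios": float(ratio.mean()),
        "small_telescope_passes": int(table["small_telescope_pass"].sum()),
        "meta_sig_05": int(table["meta_sig_05"].sum()),
        "meta_sig_005": int(table["meta_sig_005"].sum()),
        "pi_passes": int(table["pi_pass"].sum()),
    }
    k_top = sum(outcomes[i] for i in selection.top_ids)
    k_bot = sum(outcomes[i] for i in selection.bottom_ids)
    cont = [
        [k_top, len(selection.top_ids) - k_top],
        [k_bot, len(selection.bottom_ids) - k_bot],
    ]
    agg["top_vs_bottom_table"] = cont
    agg["fisher_p"] = ev.fisher_exact(cont)
    agg["boschloo_p"] = ev.boschloo(cont)
    z, p_w = ev.wilcoxon_signed_rank(d_o, d_r)
    agg["wilcoxon_d_o_vs_d_r"] = {"z": z, "p": p_w}
    agg.update(evaluate_forecasts(prices, survey, outcomes))
    return agg


# ---------------------------------------------------------------------------
# orchestration


def run_experiment(
    config: GeneratorConfig,
    seed: int,
    outdir: Optional[Path] = None,
) -> ExperimentReport:
    """Run the full synthetic decision-market replication experiment.

    Deterministic given ``config`` and ``seed``; the global seed is
    expanded into one substream per stage (population, forecasters,
    trading, random-tier draw, replications).
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(5)]
    rng_pop, rng_fore, rng_trade, rng_select, rng_rep = streams

    studies = generate_study_population(config, rng_pop)
    by_id = {s.study_id: s for s in studies}

    beliefs, survey_means = simulate_forecasters(studies, config, rng_fore)
    trade_log, prices, ledgers = simulate_trading(
        beliefs, config, rng_trade, return_ledgers=True
    )

    selection = select_studies(
        prices.to_dict(),
        k_top=config.k_top,
        k_bottom=config.k_bottom,
        n_random=config.n_random,
        seed=rng_select,
    )

    pairs: List[StudyPair] = []
    for sid in selection.selected_ids:
        study = by_id[sid]
        rep = simulate_replication(study, study.planned_n_r, rng_rep, alpha=config.alpha)
        pairs.append(StudyPair.from_summaries(study.original, rep))

    reports = [indicator_battery(p) for p in pairs]
    aggregates = _aggregate(pairs, reports, selection, prices.to_dict(), survey_means.to_dict())
    outcomes = {r.study_id: bool(r.sig_replicated) for r in reports}
    payouts = settle_market(ledgers, selection, outcomes)

    cfg_dict = dataclasses.asdict(config)
    metadata = {
        "seed": int(seed),
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_trades": int(len(trade_log)),
    }

    report = ExperimentReport(
        selection=selection,
        final_prices=prices,
        survey_means=survey_means,
        indicator_table=indicator_frame(reports),
        aggregates=aggregates,
        payouts=payouts,
        metadata=metadata,
    )
    if outdir is not None:
        write_report(report, Path(outdir), studies, pairs, trade_log)
    return report


def write_report(
    report: ExperimentReport,
    outdir: Path,
    studies: Optional[Sequence[SyntheticStudy]] = None,
    pairs: Optional[Sequence[StudyPair]] = None,
    trade_log: Optional[pd.DataFrame] = None,
) -> None:
    """Persist all experiment outputs as delimited text / JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if studies is not None or pairs is not None:
        summaries: List[TestSummary] = []
        if studies is not None:
            summaries.extend(s.original for s in studies)
        if pairs is not None:
            summaries.extend(p.replication for p in pairs)
        write_study_table(summaries, outdir / "study_table.csv")
    report.indicator_table.to_csv(outdir / "indicators.csv")
    pd.DataFrame(
        {
            "final_price": report.final_prices,
            "survey_mean_belief": report.survey_means,
        }
    ).rename_axis("study_id").to_csv(outdir / "forecasts.csv")
    if trade_log is not None:
        with open(outdir / "trades.jsonl", "w") as fh:
            for rec in trade_log.to_dict("records"):
                fh.write(json.dumps(rec) + "\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
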