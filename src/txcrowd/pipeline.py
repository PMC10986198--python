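"""End-to-end pipeline: generate or load inputs, filter, classify, resolve,
assign, analyze, fit, and report — with an auditable campaign funnel and a
reproducibility manifest.  Identical config + seed yields byte-identical
artifacts.
"""
from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from . import geo as geo_mod
from . import irr as irr_mod
from . import race as race_mod
from . import states as states_mod
from . import synthetic
from .config import RunConfig
from .constants import RACE_LEVELS
from .organs import OrganLexicon, classify_stories

_FLOAT_FMT = "%.10g"

STAGES = [
    "inputs", "deduplicate", "exclusions", "classify_organs",
    "resolve_locations", "assign_race", "state_analysis", "irr_models",
]


def percent_share(count: float, total: float, decimals: int = 0) -> float:
    """Printed percentage share: 100 x count/total, half-up rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) / Decimal(total) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class Table1:
    """Counts, shares, and outcome summaries by race/ethnicity."""

    campaign_counts: dict[str, int]
    solid_counts: dict[str, int]
    wla_counts: dict[str, float]
    outcome_summary: pd.DataFrame
    outcome_tests: pd.DataFrame
    multi_zip_count: int = 0

    def shares(self, which: str = "campaigns", decimals: int = 0) -> dict[str, float]:
        counts = {"campaigns": self.campaign_counts, "solid": self.solid_counts,
                  "wla": self.wla_counts}[which]
        total = sum(counts.values())
        return {r: percent_share(counts[r], total, decimals) for r in counts}

    def multi_zip_share(self, decimals: int = 1) -> float:
        return percent_share(self.multi_zip_count, sum(self.campaign_counts.values()), decimals)

    def to_text(self) -> str:
        lines = ["Campaigns, campaign outcomes, and waiting-list additions, by race/ethnicity", ""]
        for title, counts in (
            ("Campaigns", self.campaign_counts),
            ("Solid-organ campaigns", self.solid_counts),
            ("Solid-organ waiting-list additions", self.wla_counts),
        ):
            total = sum(counts.values())
            shares = {r: percent_share(counts[r], total) for r in counts}
            row = "  ".join(f"{r} {counts[r]:.0f} ({shares[r]:.0f}%)" for r in RACE_LEVELS if r in counts)
            lines.append(f"{title}, n = {total:.0f}: {row}")
        lines.append("")
        for outcome, grp in self.outcome_summary.groupby("outcome", sort=False):
            test = self.outcome_tests[self.outcome_tests["outcome"] == outcome]
            p = float(test["p_F"].iloc[0]) if len(test) else float("nan")
            cells = "  ".join(
                f"{row.race}: {row.median:.1f} ({row.q1:.1f}-{row.q3:.1f})"
                for row in grp.itertuples()
            )
            lines.append(f"{outcome} median (IQR): {cells}  [p = {p:.3g}]")
        return "\n".join(lines)


def report_table1(
    analysis: pd.DataFrame,
    assignments: pd.DataFrame,
    panel_study: pd.DataFrame,
) -> Table1:
    """Build the Table-1-shaped summary from the analytic set.

    ``analysis`` is the per-campaign analytic frame (race, solid_organ flag,
    outcome columns); ``panel_study`` is the interpolated panel whose WLAs
    are summed per race over the study period.
    """
    camp = {r: int((analysis["race"] == r).sum()) for r in RACE_LEVELS}
    solid = {
        r: int(((analysis["race"] == r) & (analysis["solid_organ"] == 1)).sum())
        for r in RACE_LEVELS
    }
    wla = {
        r: float(panel_study.loc[panel_study["race"] == r, "wla"].sum())
        for r in RACE_LEVELS
        if (panel_study["race"] == r).any()
    }
    summary, tests = states_mod.group_summaries(
        analysis,
        ["amount_raised", "n_donations", "goal", "success_rate", "average_donation"],
    )
    multi = int(assignments["multi_category"].sum()) if "multi_category" in assignments else 0
    return Table1(
        campaign_counts=camp, solid_counts=solid, wla_counts=wla,
        outcome_summary=summary, outcome_tests=tests, multi_zip_count=multi,
    )


@dataclass
class PipelineResult:
    """Everything a run produced: manifest, funnel, frames, fitted models."""

    manifest: dict
    outdir: pathlib.Path
    analysis: pd.DataFrame
    table1: Table1
    audit: corpus_mod.ExclusionAudit
    irr_results: dict[str, irr_mod.IRRResults]
    slopes: pd.DataFrame
    sensitivities: dict[str, pd.DataFrame] = dc_field(default_factory=dict)


def _write(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(
    config: RunConfig,
    outdir: str | pathlib.Path,
    input_dir: str | pathlib.Path | None = None,
) -> PipelineResult:
    """Execute all stages in order; any failure aborts with the stage name."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    stage = "inputs"
    try:
        if input_dir is not None:
            inp = pathlib.Path(input_dir)
            gazetteer = geo_mod.read_gazetteer(str(inp / "gazetteer.csv"))
            name_frame = pd.read_csv(inp / "name_table.csv",
                                     dtype={"first": str, "last": str, "zip": str})
            records = corpus_mod.read_corpus_csv(str(inp / "corpus.csv"))
            panel = states_mod.read_panel(str(inp / "state_panel.csv"))
        else:
            gazetteer = synthetic.generate_gazetteer(config.truth)
            name_frame = synthetic.generate_name_table(config.truth, gazetteer)
            records, _truth = synthetic.generate_campaigns(config.truth, gazetteer, name_frame)
            panel = synthetic.generate_state_panel(config.truth)
        name_table = race_mod.NameProbabilityTable(name_frame)
        stage_counts["inputs"] = len(records)

        stage = "deduplicate"
        deduped = corpus_mod.deduplicate(records)
        stage_counts["deduplicate"] = len(deduped)

        stage = "exclusions"
        filtered, audit = corpus_mod.apply_exclusions(deduped, config.exclusions)
        stage_counts["exclusions"] = len(filtered)
        _write(audit.to_frame(), out / "exclusion_audit.csv")
        (out / "exclusion_audit.txt").write_text(audit.to_text() + "\n")

        stage = "classify_organs"
        lexicon = OrganLexicon.default()
        organ_labels = pd.Series(
            classify_stories(filtered["story"], lexicon), index=filtered.index, name="organ_label"
        )
        stage_counts["classify_organs"] = int((organ_labels != "missing").sum())
        _write(pd.DataFrame({"url": filtered["url"], "organ_label": organ_labels}),
               out / "organ_labels.csv")

        stage = "resolve_locations"
        geo = geo_mod.resolve_corpus(filtered, gazetteer)
        stage_counts["resolve_locations"] = int(geo["state"].notna().sum())
        _write(
            pd.DataFrame({"url": filtered["url"], "status": geo["status"],
                          "state": geo["state"], "source": geo["source"],
                          "n_zips": geo["zip_codes"].map(len)}),
            out / "geo_resolution.csv",
        )

        stage = "assign_race"
        assignments = race_mod.assign_corpus(
            filtered, geo["zip_codes"], name_table, tau=config.certainty_threshold
        )
        stage_counts["assign_race"] = len(assignments)
        _write(assignments, out / "race_assignments.csv")

        stage = "state_analysis"
        panel_study = states_mod.interpolate_study_period(panel)
        panel_ok, dropped = states_mod.filter_sufficient(panel_study, config.min_population)
        merged = filtered.assign(
            organ_label=organ_labels, state_resolved=geo["state"].to_numpy()
        ).merge(assignments[["url", "race", "score", "concordant", "passes_threshold"]],
                on="url", how="left")
        outcomes = corpus_mod.compute_outcomes(merged)
        merged = pd.concat(
            [merged, outcomes[["amount_raised", "success_rate", "average_donation"]]], axis=1
        )
        merged["goal"] = merged["goal_cents"] / 100.0
        merged["solid"] = merged["organ_label"].isin(lexicon.solid)

        state_pop = (
            panel_ok.groupby(["state", "race"])
            .agg(population=("population", "mean"), wla=("wla", "sum"),
                 uninsured_rate=("uninsured_rate", "mean"))
            .reset_index()
        )
        solid_counts = (
            merged.loc[merged["solid"] & merged["race"].notna() & merged["state_resolved"].notna()]
            .groupby(["state_resolved", "race"]).size().rename("campaigns").reset_index()
            .rename(columns={"state_resolved": "state"})
        )
        rates = state_pop.merge(solid_counts, on=["state", "race"], how="left")
        rates["campaigns"] = rates["campaigns"].fillna(0.0)
        rates["campaigns_per_100k"] = states_mod.per_100k(rates["campaigns"], rates["population"])
        rates["wla_per_100k"] = states_mod.per_100k(rates["wla"], rates["population"])
        slope_races = [r for r in ("White", "Black", "Hispanic")
                       if (rates["race"] == r).sum() >= 3]
        slope_fits = states_mod.activity_slopes(rates[rates["race"].isin(slope_races)])
        slopes = states_mod.slopes_to_frame(slope_fits)
        stage_counts["state_analysis"] = len(rates)
        _write(rates, out / "state_rates.csv")
        _write(slopes, out / "state_slopes.csv")
        _write(pd.DataFrame(dropped, columns=["state", "race"]), out / "suppressed_cells.csv")

        stage = "irr_models"
        q4_wla = irr_mod.quartile_flags(rates, "wla_per_100k").set_index(["state", "race"])["q4"]
        q4_unins = irr_mod.quartile_flags(rates, "uninsured_rate").set_index(["state", "race"])["q4"]
        medicaid = panel.groupby("state")["medicaid_expansion"].first()

        analysis = merged.loc[merged["race"].notna() & merged["state_resolved"].notna()].copy()
        analysis["state"] = analysis["state_resolved"]
        idx = pd.MultiIndex.from_frame(analysis[["state", "race"]])
        analysis["q4_wla"] = q4_wla.reindex(idx, fill_value=False).to_numpy(dtype=float)
        analysis["q4_unins"] = q4_unins.reindex(idx, fill_value=False).to_numpy(dtype=float)
        analysis["medicaid_expansion"] = (
            medicaid.reindex(analysis["state"], fill_value=False).to_numpy(dtype=float)
        )
        fraud_thr = float(analysis["fraud_score"].quantile(config.fraud_quantile))
        covs = corpus_mod.build_covariates(
            analysis, analysis["organ_label"], fraud_thr,
            analysis[["q4_wla", "q4_unins", "medicaid_expansion"]],
        )
        overlap = [c for c in covs.columns if c in analysis.columns]
        analysis = pd.concat([analysis.drop(columns=overlap), covs], axis=1)
        analysis = analysis.loc[~analysis["model_exclude"]].reset_index(drop=True)

        families = {"amount_raised": config.family, "success_rate": "poisson",
                    "average_donation": config.family}
        irr_results: dict[str, irr_mod.IRRResults] = {}
        sensitivities: dict[str, pd.DataFrame] = {}
        for outcome, family in families.items():
            model = irr_mod.IRRModel.from_dataframe(
                analysis.dropna(subset=[outcome]), outcome,
                irr_mod.DEFAULT_COVARIATES, cluster="state", family=family,
            )
            res = model.fit()
            irr_results[outcome] = res
            _write(res.to_frame(), out / f"irr_{outcome}.csv")
            (out / f"irr_{outcome}.txt").write_text(res.summary() + "\n")
            if config.run_sensitivities:
                sens = irr_mod.run_sensitivities(
                    analysis.dropna(subset=[outcome]), outcome, family=family
                )
                sensitivities[outcome] = sens
                _write(sens, out / f"sensitivities_{outcome}.csv")
        stage_counts["irr_models"] = int(irr_results["amount_raised"].nobs)

        table1 = report_table1(analysis, assignments, panel_study)
        (out / "table1.txt").write_text(table1.to_text() + "\n")
        _write(table1.outcome_summary, out / "table1_summary.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "seed": config.truth.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": [{"stage": s, "rows": stage_counts.get(s)} for s in STAGES],
        "funnel": {
            "found": stage_counts["inputs"],
            "deduplicated": stage_counts["deduplicate"],
            "passed_exclusions": stage_counts["exclusions"],
            "analytic_set": stage_counts["irr_models"],
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        manifest=manifest, outdir=out, analysis=analysis, table1=table1,
        audit=audit, irr_results=irr_results, slopes=slopes, sensitivities=sensitivities,
    )
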