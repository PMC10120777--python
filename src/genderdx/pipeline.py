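"""End-to-end pipeline: simulate/load -> split -> filter -> screen ->
score -> outcome models -> sex-vs-gender comparison -> reports.

Every stage logs rows in/out (the complete-case audit) and writes its
table to the output directory; the effective configuration is echoed
there as well.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes as codes_mod
from . import discharge as discharge_mod
from . import inference
from . import io as io_mod
from . import mortality as mortality_mod
from . import score as score_mod
from . import simulate as sim_mod
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, fully-overridable pipeline configuration."""

    cohort_path: str | None = None
    lifetable_path: str | None = None
    outdir: str = "genderdx_output"
    seed: int = 1
    simulate: bool = True
    n_persons: int = 20_000
    split_proportions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    alpha: float = 0.05
    correction: str = "bh"  # bh | bonferroni
    screen_method: str = "wald"  # wald | lrt
    mortality_form: str = "multiplicative"  # multiplicative | additive
    income_handling: str = "linear"  # linear | categorical
    los_transform: str = "identity"  # identity | log
    code_delimiter: str = "|"
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if abs(sum(self.split_proportions) - 1.0) > 1e-9:
            raise InvalidConfigError("split proportions must sum to 1")
        if not (0.0 <= self.alpha < 1.0):
            raise InvalidConfigError("alpha must lie in [0, 1)")
        if self.correction not in ("bh", "bonferroni"):
            raise InvalidConfigError("correction must be 'bh' or 'bonferroni'")
        if not self.simulate and (self.cohort_path is None or self.lifetable_path is None):
            raise InvalidConfigError("need cohort_path and lifetable_path unless simulating")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "split_proportions" in raw:
            raw["split_proportions"] = tuple(raw["split_proportions"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["split_proportions"] = list(self.split_proportions)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _stage(name: str, rows_in: int, rows_out: int) -> None:
    logger.info(
        "stage=%s time=%s rows_in=%d rows_out=%d",
        name,
        time.strftime("%Y-%m-%dT%H:%M:%S"),
        rows_in,
        rows_out,
    )


def _controls(config: PipelineConfig, base: list[str], data: pd.DataFrame) -> list[str]:
    controls = list(base)
    if config.income_handling == "categorical":
        controls.remove("income_quintile")
        for q in (2, 3, 4, 5):
            col = f"income_q{q}"
            data[col] = (data["income_quintile"] == q).astype(float)
            controls.append(col)
    if config.los_transform == "log" and "los_days" in controls:
        data["log_los"] = np.log(data["los_days"])
        controls[controls.index("los_days")] = "log_los"
    return controls


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the in-memory results bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "effective_config.yaml")
    results: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_config = sim_mod.SimConfig(
            n_persons=config.n_persons, seed=config.seed, **config.sim_overrides
        )
        cohort, lifetable, truth = sim_mod.simulate_cohort(sim_config)
        sim_mod.write_cohort(cohort, outdir / "cohort.csv")
        lifetable.to_csv(outdir / "lifetable.csv")
        truth.to_json(outdir / "ground_truth.json")
        results["truth"] = truth
        _stage("simulate", 0, len(cohort))
    else:
        cohort = io_mod.read_cohort(config.cohort_path, config.code_delimiter)
        lifetable = io_mod.read_lifetable(config.lifetable_path)
        _stage("load", 0, len(cohort))

    # --- split / matrix / filter / screen ---------------------------------
    fold = codes_mod.split_cohort(cohort, config.seed, config.split_proportions)
    cohort = cohort.assign(fold=fold)
    matrices = {
        f: codes_mod.build_indicator_matrix(
            cohort[cohort["fold"] == f], config.code_delimiter
        )
        for f in codes_mod.SPLIT_LABELS
    }
    sexes = {
        f: cohort.loc[cohort["fold"] == f, "sex"].to_numpy()
        for f in codes_mod.SPLIT_LABELS
    }
    kept = codes_mod.filter_codes(
        matrices["train"], sexes["train"], matrices["valid"], sexes["valid"]
    )
    _stage("filter_codes", len(matrices["train"].vocabulary), len(kept))

    train_m = matrices["train"].subset_codes(kept)
    valid_m = matrices["valid"].subset_codes(kept)
    screen_train = score_mod.univariate_screen(
        train_m, sexes["train"], config.screen_method
    )
    screen_valid = score_mod.univariate_screen(
        valid_m, sexes["valid"], config.screen_method
    )
    selection = score_mod.select_codes(
        screen_train, screen_valid, config.alpha, config.correction
    )
    io_mod.write_screen_table(selection, outdir / "screen_results.csv")
    selected = selection.loc[selection["selected"] == 1, "code"].tolist()
    _stage("select_codes", len(kept), len(selected))
    results["selection"] = selection

    # --- gender score ------------------------------------------------------
    model = score_mod.fit_score_model(train_m, sexes["train"], selected)
    model.to_json(outdir / "gender_score_model.json")
    results["score_model"] = model
    scores = np.empty(len(cohort))
    for f in codes_mod.SPLIT_LABELS:
        mask = (cohort["fold"] == f).to_numpy()
        scores[mask] = score_mod.score_persons(model, matrices[f])
    cohort["gender_score"] = scores
    cohort.to_csv(outdir / "cohort_scored.csv", index=False)
    _stage("score_persons", len(cohort), len(cohort))

    test = cohort[cohort["fold"] == "test"]
    score_constant = np.ptp(test["gender_score"].to_numpy()) < 1e-12
    if score_constant:
        logger.warning(
            "gender score is constant (empty selection); score-based models skipped"
        )

    # --- mortality ---------------------------------------------------------
    mort_set = mortality_mod.build_mortality_set(test, lifetable, "gender_score")
    _stage("mortality_set", len(test), len(mort_set))
    mort_contexts = {}
    lrt_rows = []
    if len(mort_set) and mort_set["event"].sum() > 0:
        specs = {"model1": True, "model2": not score_constant, "model3": not score_constant}
        all_models = mortality_mod.run_mortality_models(
            mort_set, "gender_score", config.mortality_form
        ) if specs["model2"] else {
            "model1": mortality_mod.fit_excess_poisson(
                mort_set,
                ["sex"] + mortality_mod.MORTALITY_CONTROLS,
                config.mortality_form,
                "mortality model1",
            )
        }
        mort_contexts = all_models
        if "model3" in mort_contexts and config.mortality_form == "multiplicative":
            s_stat, s_df, s_p = inference.term_lrt(mort_contexts["model3"], "sex")
            g_stat, g_df, g_p = inference.term_lrt(
                mort_contexts["model3"], "gender_score"
            )
            lrt_rows = [
                {"model": "model3", "term": "sex", "lrt": s_stat, "df": s_df, "p": s_p},
                {
                    "model": "model3",
                    "term": "gender_score",
                    "lrt": g_stat,
                    "df": g_df,
                    "p": g_p,
                },
            ]
            results["mortality_comparison"] = inference.compare_sex_vs_gender(
                s_stat, g_stat, s_df
            )
        table = io_mod.mortality_report(
            {k: v for k, v in mort_contexts.items() if hasattr(v, "profile_loglik")},
            lrt_rows,
        )
        table.to_csv(outdir / "mortality_models.csv", index=False)
        results["mortality_models"] = mort_contexts

    # --- discharge ---------------------------------------------------------
    disc_set = discharge_mod.build_discharge_set(test, "gender_score")
    _stage("discharge_set", len(test), len(disc_set))
    disc_controls = _controls(config, discharge_mod.DISCHARGE_CONTROLS, disc_set)
    disc_contexts = {}
    if not score_constant:
        specs = {
            "model1": ["sex"] + disc_controls,
            "model2": ["gender_score"] + disc_controls,
            "model3": ["sex", "gender_score"] + disc_controls,
        }
    else:
        specs = {"model1": ["sex"] + disc_controls}
    disc_tables = []
    for name, terms in specs.items():
        ctx = discharge_mod.fit_baseline_logit(disc_set, terms, label=f"discharge {name}")
        disc_contexts[name] = ctx
        tab = discharge_mod.category_or_table(ctx, ["sex", "gender_score"])
        tab.insert(0, "model", name)
        disc_tables.append(tab)
    if "model3" in disc_contexts:
        s_stat, s_df, s_p = inference.term_lrt(disc_contexts["model3"], "sex")
        g_stat, g_df, g_p = inference.term_lrt(disc_contexts["model3"], "gender_score")
        results["discharge_comparison"] = inference.compare_sex_vs_gender(
            s_stat, g_stat, s_df
        )
    pd.concat(disc_tables).to_csv(outdir / "discharge_models.csv", index=False)
    results["discharge_models"] = disc_contexts

    if not score_constant:
        sub_fits = discharge_mod.fit_other_sublocation_models(
            disc_set, ["gender_score"] + disc_controls
        )
        sub_rows = []
        for sub, ctx in sub_fits.items():
            res = ctx.result
            coef = res.params["gender_score"]
            se = res.se("gender_score")
            sub_rows.append(
                {
                    "sublocation": sub,
                    "score_or": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - 1.959964 * se)),
                    "ci_high": float(np.exp(coef + 1.959964 * se)),
                    "n": res.n,
                }
            )
        pd.DataFrame(sub_rows).to_csv(outdir / "sublocation_models.csv", index=False)
        results["sublocation_models"] = sub_fits

    # --- comparison report -------------------------------------------------
    comparisons = {
        k: results[k].to_dict()
        for k in ("mortality_comparison", "discharge_comparison")
        if k in results
    }
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)
    for key in ("mortality_comparison", "discharge_comparison"):
        if key in results:
            logger.info("%s: %s", key, results[key].narrative())
    results["cohort"] = cohort
    results["lifetable"] = lifetable
    return results
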