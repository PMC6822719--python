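"""Full-analysis orchestration and machine-readable reporting.

``run_analysis`` walks a validated dataset and produces, for every strain
x species x temperature x response combination of the design, the
control-corrected effect size with its paired-plate bootstrap CI and bias
plus the smoothed-logit t-test; host-specificity rows per strain; control
baseline rows; and one split-plot ANOVA table per temperature x response.

Responses analysed per regime: germination and mortality under both
regimes, seed loss under summer only.  The winter mortality ANOVA is
computed but flagged ``low-signal`` — whether it carries biological signal
is a property of the data, not of the design.

Results serialize to S2-style CSV files plus a JSON bundle that the
``report`` CLI command can re-render without recomputation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (
    bootstrap_control_mean,
    bootstrap_effect,
    bootstrap_host_specificity,
)
from .classical import (
    AnovaRow,
    AnovaTable,
    auto_smoothing_constant,
    splitplot_anova,
    t_test_vs_control,
)
from .effects import EffectKind
from .plates import (
    CONTROL,
    Dataset,
    ResponseKind,
    SeedFateError,
    Species,
    Temperature,
)

__all__ = ["AnalysisResult", "run_analysis", "write_report", "load_bundle"]

log = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "group",
    "species",
    "temperature",
    "response",
    "effect_kind",
    "logit_effect",
    "se",
    "t_stat",
    "p_value",
    "effect",
    "ci_low",
    "ci_high",
    "boot_bias",
)

SPECIES_ORDER = (Species.BRTO, Species.PLOV)


def _responses_for(temperature: Temperature) -> tuple[ResponseKind, ...]:
    if temperature is Temperature.SUMMER:
        return (ResponseKind.GERMINATION, ResponseKind.MORTALITY, ResponseKind.LOSS)
    return (ResponseKind.GERMINATION, ResponseKind.MORTALITY)


@dataclass(frozen=True)
class AnalysisResult:
    rows: pd.DataFrame
    anova: dict[tuple[Temperature, ResponseKind], AnovaTable]
    anova_flags: dict[tuple[Temperature, ResponseKind], str]
    meta: dict

    def anova_frame(self, key: tuple[Temperature, ResponseKind]) -> pd.DataFrame:
        return self.anova[key].to_dataframe()


def run_analysis(
    dataset: Dataset,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> AnalysisResult:
    """Run both analysis tracks over every cell of the design.

    Bootstrap seeds are derived deterministically from ``rng_seed`` (one
    child seed per result row, in the fixed row order), so repeated runs
    with the same seed are byte-identical.
    """
    temperatures = dataset.temperatures()
    strains = dataset.strains()
    if not strains:
        raise SeedFateError("dataset has no inoculated groups")
    if CONTROL not in dataset.groups():
        raise SeedFateError("dataset has no CONTROL group")

    # one smoothing constant per temperature x response, by the auto rule
    smoothing: dict[tuple[Temperature, ResponseKind], float] = {}
    for temp in temperatures:
        for resp in _responses_for(temp):
            smoothing[(temp, resp)] = auto_smoothing_constant(dataset, temp, resp)
            log.info(
                "smoothing constant %.6g for %s/%s",
                smoothing[(temp, resp)], temp.value, resp.value,
            )

    # enumerate rows in deterministic order, then derive one seed each
    plan: list[tuple] = []
    for temp in temperatures:
        for resp in _responses_for(temp):
            for strain in strains:
                for sp in SPECIES_ORDER:
                    plan.append(("vs_control", temp, resp, strain, sp))
    for temp in temperatures:
        for resp in _responses_for(temp):
            for strain in strains:
                plan.append(("host_specificity", temp, resp, strain, SPECIES_ORDER))
    for temp in temperatures:
        for resp in _responses_for(temp):
            for sp in SPECIES_ORDER:
                plan.append(("control_mean", temp, resp, CONTROL, sp))

    seeds = np.random.SeedSequence(rng_seed).generate_state(len(plan))
    rows = []
    for (kind, temp, resp, group, sp), seed in zip(plan, seeds):
        seed = int(seed)
        if kind == "vs_control":
            boot = bootstrap_effect(
                dataset, group, sp, temp, resp, n_reps, alpha, seed
            )
            tt = t_test_vs_control(
                dataset, group, sp, temp, resp, smoothing[(temp, resp)]
            )
            logit_eff, se, t_stat, p = tt.effect_logit, tt.se, tt.t_stat, tt.p_value
            species_label = sp.value
        elif kind == "host_specificity":
            a, b = sp
            boot = bootstrap_host_specificity(
                dataset, group, a, b, temp, resp, n_reps, alpha, seed
            )
            logit_eff = se = t_stat = p = math.nan
            species_label = f"{a.value}-{b.value}"
        else:
            boot = bootstrap_control_mean(
                dataset, sp, temp, resp, n_reps, alpha, seed
            )
            logit_eff = se = t_stat = p = math.nan
            species_label = sp.value
        log.info("analysed %s %s %s %s %s", kind, temp.value, resp.value, group,
                 species_label)
        rows.append(
            {
                "group": group,
                "species": species_label,
                "temperature": temp.value,
                "response": resp.value,
                "effect_kind": kind,
                "logit_effect": logit_eff,
                "se": se,
                "t_stat": t_stat,
                "p_value": p,
                "effect": boot.estimate,
                "ci_low": boot.ci_low,
                "ci_high": boot.ci_high,
                "boot_bias": boot.bias,
            }
        )
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))

    anova: dict[tuple[Temperature, ResponseKind], AnovaTable] = {}
    flags: dict[tuple[Temperature, ResponseKind], str] = {}
    for temp in temperatures:
        for resp in _responses_for(temp):
            table = splitplot_anova(dataset, temp, resp, smoothing[(temp, resp)])
            anova[(temp, resp)] = table
            if temp is Temperature.WINTER and resp is ResponseKind.MORTALITY:
                flags[(temp, resp)] = "low-signal"

    meta = {
        "rng_seed": int(rng_seed),
        "n_reps": int(n_reps),
        "alpha": float(alpha),
        "quantile_rule": "linear interpolation between order statistics",
        "smoothing_constants": {
            f"{t.value}/{r.value}": float(c) for (t, r), c in smoothing.items()
        },
        "software_version": __version__,
        "n_strains": len(strains),
        "n_records": len(dataset),
    }
    return AnalysisResult(rows=frame, anova=anova, anova_flags=flags, meta=meta)


# -- serialization --------------------------------------------------------


def _anova_filename(temp: Temperature, resp: ResponseKind) -> str:
    return f"anova_{temp.value}_{resp.value}.csv"


def write_report(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """Write results.csv, per-table ANOVA CSVs, metadata and a JSON bundle.

    Numeric fields are written with 17 significant digits so a round-trip
    read reproduces every value to full double precision.
    """
    if result.rows.empty:
        raise SeedFateError("refusing to write a report for empty results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    results_path = out / "results.csv"
    result.rows.to_csv(results_path, index=False, float_format="%.17g")
    written.append(results_path)

    for (temp, resp), table in sorted(
        result.anova.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        p = out / _anova_filename(temp, resp)
        table.to_dataframe().to_csv(p, index=False, float_format="%.17g")
        written.append(p)

    meta_path = out / "run_metadata.txt"
    lines = [f"{k}: {v}" for k, v in result.meta.items()]
    for (temp, resp), flag in sorted(
        result.anova_flags.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        lines.append(f"anova_flag {temp.value}/{resp.value}: {flag}")
    meta_path.write_text("\n".join(lines) + "\n")
    written.append(meta_path)

    bundle_path = out / "results_bundle.json"
    bundle_path.write_text(json.dumps(_to_bundle(result), indent=1))
    written.append(bundle_path)
    return written


def _to_bundle(result: AnalysisResult) -> dict:
    return {
        "meta": result.meta,
        "rows": result.rows.to_dict(orient="records"),
        "anova": [
            {
                "temperature": temp.value,
                "response": resp.value,
                "smoothing_constant": table.smoothing_constant,
                "degenerate": table.degenerate,
                "flag": result.anova_flags.get((temp, resp)),
                "rows": [
                    {
                        "source": r.source,
                        "ss": r.ss,
                        "df": r.df,
                        "ms": r.ms,
                        "f": r.f,
                        "p": r.p,
                    }
                    for r in table.rows
                ],
            }
            for (temp, resp), table in sorted(
                result.anova.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ],
    }


def load_bundle(path: str | Path) -> AnalysisResult:
    """Rebuild an :class:`AnalysisResult` from a saved JSON bundle."""
    doc = json.loads(Path(path).read_text())
    rows = pd.DataFrame(doc["rows"], columns=list(RESULT_COLUMNS))
    anova: dict[tuple[Temperature, ResponseKind], AnovaTable] = {}
    flags: dict[tuple[Temperature, ResponseKind], str] = {}
    for entry in doc["anova"]:
        key = (Temperature(entry["temperature"]), ResponseKind(entry["response"]))
        anova[key] = AnovaTable(
            temperature=key[0],
            response=key[1],
            smoothing_constant=entry["smoothing_constant"],
            degenerate=entry["degenerate"],
            rows=tuple(
                AnovaRow(
                    source=r["source"], ss=r["ss"], df=r["df"], ms=r["ms"],
                    f=r["f"], p=r["p"],
                )
                for r in entry["rows"]
            ),
        )
        if entry.get("flag"):
            flags[key] = entry["flag"]
    return AnalysisResult(rows=rows, anova=anova, anova_flags=flags, meta=doc["meta"])
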