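"""End-to-end run: read -> eligibility -> equations -> concordance + dosing -> reports.

A run is fully reproducible from (input table, RunConfig): the config is
serialised verbatim into the output directory and hashed into the manifest,
no timestamps enter any report, and every input row is accounted for as
retained or excluded. All artifacts are written twice, human-readable
(delimited text) and machine-readable (``report.json``).

The primary comparison scale is absolute mL/min (non-indexed), matching the
units of the Calvert formula; BSA-indexed eGFR values are carried alongside
in the per-determination table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, load_cohort
from .concordance import bland_altman, contingency, stratify, summarize
from .dosing import dose_error_rates
from .equations import DEFAULT_SELECTION, MarkerPanel, evaluate_all
from .errors import ConfigurationError, GfrConcordError
from .units import Anthropometrics

DEFAULT_SUBGROUPS = ("sex", "bmi_category", "metastatic")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on besides the input table itself."""

    input_path: str
    output_dir: str
    equations: tuple = DEFAULT_SELECTION
    target_auc: float = 5.0
    p30_tol: float = 0.30
    p15_tol: float = 0.15
    subgroup_keys: tuple = DEFAULT_SUBGROUPS
    cap_reference: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        cohort = CohortConfig(**raw.pop("cohort", {}))
        try:
            return cls(cohort=cohort, **{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
            })
        except TypeError as exc:
            raise ConfigurationError(f"invalid run config: {exc}") from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["equations"] = list(self.equations)
        d["subgroup_keys"] = list(self.subgroup_keys)
        return d


def apply_equations(determinations: pd.DataFrame, selection=DEFAULT_SELECTION) -> pd.DataFrame:
    """Per-determination eGFR table: one non-indexed (and, where the equation
    is BSA-indexed, one indexed) column per equation id."""
    rows = []
    for _, rec in determinations.iterrows():
        panel = MarkerPanel(age=float(rec["age_years"]), sex=rec["sex"],
                            scr=float(rec["scr_mg_dl"]), scys=float(rec["scys_mg_l"]))
        anthro = Anthropometrics(float(rec["height_cm"]), float(rec["weight_kg"]))
        out = {}
        for r in evaluate_all(panel, anthro, selection):
            out[f"egfr_{r.equation_id}"] = r.egfr_nonindexed
            if r.egfr_indexed is not None:
                out[f"egfr_{r.equation_id}_indexed"] = r.egfr_indexed
        rows.append(out)
    return pd.DataFrame(rows, index=determinations.index)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GfrConcordError as exc:
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the structured report (the content of ``report.json``). Nothing
    is written until every stage has succeeded, so a failure leaves no
    partial outputs behind.
    """
    determinations, exclusions = _stage("cohort")(load_cohort)(
        config.input_path, config.cohort)
    if determinations.empty:
        raise GfrConcordError("stage 'cohort' failed: no determinations retained")
    egfr = _stage("equations")(apply_equations)(determinations, config.equations)
    mgfr = determinations["mgfr"].to_numpy()

    summaries, band_tables, ba_pairs, ba_summaries = {}, {}, {}, {}
    subgroup_summaries = {}
    for eq in config.equations:
        e = egfr[f"egfr_{eq}"].to_numpy()
        s = summarize(e, mgfr)
        summaries[eq] = dataclasses.asdict(s)
        band_tables[eq] = contingency(e, mgfr)
        pairs, ba = bland_altman(e, mgfr)
        ba_pairs[eq], ba_summaries[eq] = pairs, ba
        subgroup_summaries[eq] = {
            key: {k: dataclasses.asdict(v) for k, v in
                  stratify(e, mgfr, determinations[key].to_numpy()).items()}
            for key in config.subgroup_keys
        }

    dosing_overall, dosing_subgroups = {}, {}
    for eq in config.equations:
        e = egfr[f"egfr_{eq}"].to_numpy()
        dosing_overall[eq] = dose_error_rates(
            mgfr, e, config.target_auc, cap_reference=config.cap_reference)
        dosing_subgroups[eq] = {
            key: dose_error_rates(mgfr, e, config.target_auc,
                                  strata=determinations[key].to_numpy(),
                                  cap_reference=config.cap_reference)
            for key in config.subgroup_keys
        }

    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "n_input_rows": int(len(determinations) + len(exclusions)),
        "n_retained": int(len(determinations)),
        "n_excluded": int(len(exclusions)),
        "exclusions_by_rule": exclusions["rule"].value_counts().to_dict()
        if len(exclusions) else {},
    }
    report = {
        "manifest": manifest,
        "concordance": summaries,
        "concordance_subgroups": subgroup_summaries,
        "band_agreement": {
            eq: {"percent_agreement": bt.percent_agreement,
                 "row_percent": bt.row_percent.round(6).tolist(),
                 "row_counts": bt.row_counts.tolist(),
                 "labels": list(bt.labels)}
            for eq, bt in band_tables.items()
        },
        "bland_altman": ba_summaries,
        "dosing": {eq: df.to_dict(orient="records") for eq, df in dosing_overall.items()},
        "dosing_subgroups": {
            eq: {key: df.to_dict(orient="records") for key, df in by_key.items()}
            for eq, by_key in dosing_subgroups.items()
        },
    }

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(config_yaml)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    pd.DataFrame(summaries).T.rename_axis("equation").to_csv(outdir / "concordance_summary.csv")
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    determinations.join(egfr).to_csv(outdir / "determinations.csv", index=False)
    for eq, bt in band_tables.items():
        bt.to_frame().rename_axis("mgfr_band").to_csv(outdir / f"contingency_{eq}.csv")
    for eq, pairs in ba_pairs.items():
        pairs.to_csv(outdir / f"bland_altman_{eq}.csv", index=False)
    dosing_rows = []
    for eq, df in dosing_overall.items():
        dosing_rows.append(df.assign(equation=eq, subgroup_key="overall"))
    for eq, by_key in dosing_subgroups.items():
        for key, df in by_key.items():
            dosing_rows.append(df.assign(equation=eq, subgroup_key=key))
    pd.concat(dosing_rows, ignore_index=True).to_csv(outdir / "dosing_rates.csv", index=False)
    return report
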