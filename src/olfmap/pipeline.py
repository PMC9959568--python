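"""End-to-end orchestration: cohort -> scoring -> statistics -> semantic map.

A run takes a cohort from one of three sources (seeded generator, the
deterministic fixture, or a CSV file), derives every classification the
analysis needs, and emits:

1. per-sex descriptives (mean +/- SE) for the continuous variables;
2. count tables: weight class by sex, metabolic conditions by sex,
   olfactory status overall and by sex;
3. Pearson correlations of the olfactory scores (TDI, T, D, I) against
   systolic blood pressure, fasting glucose, HDL, triglycerides and the
   Mediterranean Diet Score — overall and per sex;
4. chi-square and Fisher exact sex comparisons of olfactory status;
5. the Auto-CM semantic map (edge-list TSV, GraphML, DOT) with hubs,
   central node and energy;
6. a machine-readable run manifest.

All randomness flows from the single config seed, so identical configs
give identical report bundles (manifest timestamp aside).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocm import DEFAULT_AGE_CUTOFF, encode_variables, strengths_frame, train_autocm
from .clinical import (
    MDS_DEFAULT_CUTOFF,
    classify_idf_flags,
    classify_mets,
    compute_bmi,
    score_mds,
)
from .cohort import CohortParams, PatientRecord, generate_cohort, make_fixture_cohort
from .errors import ParameterError, SchemaError
from .olfaction import OlfactoryCutoffs, classify_olfactory, compose_tdi
from .semantic import build_semantic_map, export_map
from .stats import chi_square_2x2, fisher_exact_2x2, mean_se, pearson_r

log = logging.getLogger("olfmap")

CSV_COLUMNS = (
    ["id", "sex", "age", "height", "weight", "wc", "sbp", "dbp", "fpg", "hdl", "tg"]
    + ["treated_diabetes", "treated_dyslipidemia", "treated_hypertension", "smoker"]
    + [f"mds_c{k}" for k in range(1, 12)]
    + ["t_score", "d_count", "i_count"]
)
OPTIONAL_CLASS_COLUMNS = ["class_t", "class_d", "class_i", "class_tdi"]
_FLAG_COLUMNS = [
    "treated_diabetes",
    "treated_dyslipidemia",
    "treated_hypertension",
    "smoker",
]

DESCRIPTIVE_FIELDS = [
    "age", "height", "weight", "bmi", "wc", "sbp", "dbp", "fpg", "hdl", "tg",
    "mds", "tdi", "t", "d", "i",
]
CORRELATION_TARGETS = ["sbp", "fpg", "hdl", "tg", "mds"]
OLFACTORY_SCORES = ["TDI", "T", "D", "I"]


@dataclass
class AutoCMParams:
    C: float = 1.0
    lr: float = 0.01
    max_epochs: int = 1000
    tol: float = 1e-6


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    mode: str = "generate"                 # generate | fixture | csv
    csv_path: Optional[str] = None
    cohort: CohortParams = field(default_factory=CohortParams)
    cutoffs: OlfactoryCutoffs = field(default_factory=OlfactoryCutoffs)
    age_cutoff: float = DEFAULT_AGE_CUTOFF
    mds_cutoff: float = MDS_DEFAULT_CUTOFF
    autocm: AutoCMParams = field(default_factory=AutoCMParams)
    out_dir: str = "olfmap_run"
    seed: Optional[int] = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("generate", "fixture", "csv"):
            raise ParameterError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv" and not self.csv_path:
            raise ParameterError("csv mode requires csv_path")
        if self.mode == "generate" and self.seed is None:
            raise ParameterError("generate mode requires a seed")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            known = {f.name for f in dc_fields(CohortParams)}
            bad = set(kwargs["cohort"]) - known
            if bad:
                raise ParameterError(f"unknown cohort parameter(s): {sorted(bad)}")
            kwargs["cohort"] = CohortParams(**kwargs["cohort"])
        if "cutoffs" in kwargs and isinstance(kwargs["cutoffs"], dict):
            kwargs["cutoffs"] = OlfactoryCutoffs(**kwargs["cutoffs"])
        if "autocm" in kwargs and isinstance(kwargs["autocm"], dict):
            kwargs["autocm"] = AutoCMParams(**kwargs["autocm"])
        known = {f.name for f in dc_fields(cls)}
        bad = set(kwargs) - known
        if bad:
            raise ParameterError(f"unknown config key(s): {sorted(bad)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Cohort CSV round trip
# ---------------------------------------------------------------------------


def write_cohort_csv(records: list[PatientRecord], path) -> Path:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in CSV_COLUMNS if not c.startswith("mds_c")}
        for k, comp in enumerate(r.mds_components, start=1):
            row[f"mds_c{k}"] = comp
        for c in OPTIONAL_CLASS_COLUMNS:
            row[c] = getattr(r, c)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS + OPTIONAL_CLASS_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> list[PatientRecord]:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty cohort file") from None
    if frame.empty:
        raise SchemaError(f"{path}: cohort file holds no records")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for ix, row in frame.iterrows():
        numeric = [
            "age", "height", "weight", "wc", "sbp", "dbp", "fpg", "hdl", "tg",
            "t_score", "d_count", "i_count",
        ] + [f"mds_c{k}" for k in range(1, 12)]
        for c in numeric:
            try:
                float(row[c])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: non-numeric cell at row {ix}, column {c!r}: {row[c]!r}"
                ) from None
        rec = PatientRecord(
            id=str(row["id"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            wc=float(row["wc"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            fpg=float(row["fpg"]),
            hdl=float(row["hdl"]),
            tg=float(row["tg"]),
            treated_diabetes=bool(row["treated_diabetes"]),
            treated_dyslipidemia=bool(row["treated_dyslipidemia"]),
            treated_hypertension=bool(row["treated_hypertension"]),
            smoker=bool(row["smoker"]),
            mds_components=tuple(
                int(row[f"mds_c{k}"]) for k in range(1, 12)
            ),
            t_score=float(row["t_score"]),
            d_count=int(row["d_count"]),
            i_count=int(row["i_count"]),
            **{
                c: (None if pd.isna(row.get(c)) else str(row[c]))
                for c in OPTIONAL_CLASS_COLUMNS
                if c in frame.columns
            },
        )
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Classification layer
# ---------------------------------------------------------------------------


def derive_profiles(
    records: list[PatientRecord],
    cutoffs: OlfactoryCutoffs | None = None,
    mds_cutoff: float = MDS_DEFAULT_CUTOFF,
    use_stored_classes: bool = True,
) -> pd.DataFrame:
    """Classify every record; one row per retained subject.

    Records with BMI below 25 do not belong to a weight-excess cohort and
    are dropped with a log note. Stored olfactory classes take precedence
    over cut-off re-derivation when present and ``use_stored_classes``.
    """
    cutoffs = cutoffs or OlfactoryCutoffs()
    rows = []
    for rec in records:
        bmi, bmi_class = compute_bmi(rec.weight, rec.height)
        if bmi_class is None:
            log.info("excluding %s: BMI %.1f below the weight-excess range", rec.id, bmi)
            continue
        flags = classify_idf_flags(rec)
        mds_total, mds_high = score_mds(rec.mds_components, cutoff=mds_cutoff)
        tdi = compose_tdi(rec.t_score, rec.d_count, rec.i_count)
        scores = {"T": rec.t_score, "D": rec.d_count, "I": rec.i_count, "TDI": tdi}
        classes = {}
        for test in OLFACTORY_SCORES:
            stored = getattr(rec, f"class_{test.lower()}")
            if use_stored_classes and stored is not None:
                classes[test] = stored
            else:
                classes[test] = classify_olfactory(scores[test], test, cutoffs)
        rows.append(
            {
                "id": rec.id,
                "sex": rec.sex,
                "age": rec.age,
                "smoker": rec.smoker,
                "bmi": bmi,
                "bmi_class": bmi_class,
                "wc_elevated": flags.wc_elevated,
                "high_bp": flags.high_bp,
                "high_gly": flags.high_gly,
                "high_tg": flags.high_tg,
                "low_hdl": flags.low_hdl,
                "mets": classify_mets(flags),
                "mds_total": mds_total,
                "mds_high": mds_high,
                "sbp": rec.sbp,
                "dbp": rec.dbp,
                "fpg": rec.fpg,
                "hdl": rec.hdl,
                "tg": rec.tg,
                "height": rec.height,
                "weight": rec.weight,
                "wc": rec.wc,
                "t_score": rec.t_score,
                "d_count": rec.d_count,
                "i_count": rec.i_count,
                "tdi": tdi,
                "class_t": classes["T"],
                "class_d": classes["D"],
                "class_i": classes["I"],
                "class_tdi": classes["TDI"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_DESC_SOURCE = {
    "mds": "mds_total", "tdi": "tdi", "t": "t_score", "d": "d_count", "i": "i_count",
}


def descriptives_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sex mean +/- SE table of the continuous variables."""
    rows = []
    for name in DESCRIPTIVE_FIELDS:
        col = _DESC_SOURCE.get(name, name)
        row = {"variable": name}
        for sex in ("F", "M"):
            vals = profiles.loc[profiles["sex"] == sex, col]
            if len(vals) >= 2:
                m, se = mean_se(vals)
            else:
                m, se = (float(vals.iloc[0]) if len(vals) else np.nan), np.nan
            row[f"mean_{sex}"] = m
            row[f"se_{sex}"] = se
        rows.append(row)
    return pd.DataFrame(rows)


def _count_pct(frame: pd.DataFrame, mask: pd.Series, sex: str) -> tuple[int, float]:
    sel = frame["sex"] == sex
    n = int((mask & sel).sum())
    denom = int(sel.sum())
    return n, round(100.0 * n / denom, 2) if denom else float("nan")


def count_tables(profiles: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Weight-class, condition, and olfactory-status count tables."""
    out: dict[str, pd.DataFrame] = {}
    rows = []
    for cls in ("overweight", "obesity"):
        mask = profiles["bmi_class"] == cls
        rec = {"bmi_status": cls}
        for sex in ("F", "M"):
            rec[f"n_{sex}"], rec[f"pct_{sex}"] = _count_pct(profiles, mask, sex)
        rows.append(rec)
    out["bmi_by_sex"] = pd.DataFrame(rows)

    conditions = [
        ("hypertension", profiles["high_bp"]),
        ("hyperglycemia", profiles["high_gly"]),
        ("low_hdl", profiles["low_hdl"]),
        ("high_tg", profiles["high_tg"]),
        ("ms", profiles["mets"]),
        ("mds_below_30", ~profiles["mds_high"]),
    ]
    rows = []
    for name, mask in conditions:
        rec = {"condition": name}
        for sex in ("F", "M"):
            rec[f"n_{sex}"], rec[f"pct_{sex}"] = _count_pct(profiles, mask, sex)
        rows.append(rec)
    out["conditions_by_sex"] = pd.DataFrame(rows)

    rows = []
    n_total = len(profiles)
    for test in OLFACTORY_SCORES:
        for status in ("normosmic", "hyposmic"):
            mask = profiles[f"class_{test.lower()}"] == status
            n = int(mask.sum())
            rows.append(
                {
                    "test": test,
                    "status": status,
                    "n": n,
                    "pct": round(100.0 * n / n_total, 2) if n_total else np.nan,
                }
            )
    out["olfactory_status"] = pd.DataFrame(rows)

    rows = []
    for test in OLFACTORY_SCORES:
        col = profiles[f"class_{test.lower()}"]
        rec: dict = {"test": test}
        counts = {}
        for sex in ("F", "M"):
            for status in ("normosmic", "hyposmic"):
                n, pct = _count_pct(profiles, col == status, sex)
                counts[(sex, status)] = n
                rec[f"{status}_{sex}"] = n
                rec[f"{status}_pct_{sex}"] = pct
        table = [
            [counts[("F", "normosmic")], counts[("F", "hyposmic")]],
            [counts[("M", "normosmic")], counts[("M", "hyposmic")]],
        ]
        try:
            chi = chi_square_2x2(table)
            fisher = fisher_exact_2x2(table)
            rec.update(
                chi_square=chi.statistic,
                chi_square_p=chi.p_value,
                fisher_p=fisher.p_value,
                significant=fisher.significant,
            )
        except Exception as exc:  # degenerate split
            rec.update(chi_square=np.nan, chi_square_p=np.nan, fisher_p=np.nan,
                       significant=False)
            log.warning("sex comparison for %s degenerate: %s", test, exc)
        rows.append(rec)
    out["olfactory_by_sex"] = pd.DataFrame(rows)
    return out


def correlation_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of each olfactory score against each clinical variable,
    overall and per sex."""
    score_col = {"TDI": "tdi", "T": "t_score", "D": "d_count", "I": "i_count"}
    target_col = {"mds": "mds_total"}
    rows = []
    for group, sel in (
        ("all", profiles.index == profiles.index),
        ("F", profiles["sex"] == "F"),
        ("M", profiles["sex"] == "M"),
    ):
        sub = profiles[sel]
        for score in OLFACTORY_SCORES:
            for target in CORRELATION_TARGETS:
                col = target_col.get(target, target)
                row = {"group": group, "olfactory_score": score, "variable": target}
                try:
                    res = pearson_r(sub[score_col[score]], sub[col])
                    row.update(r=res.statistic, p=res.p_value, significant=res.significant)
                except Exception as exc:
                    row.update(r=np.nan, p=np.nan, significant=False)
                    log.warning("correlation %s vs %s (%s): %s", score, target, group, exc)
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    config: RunConfig
    records: list[PatientRecord]
    profiles: pd.DataFrame
    tables: dict
    correlations: pd.DataFrame
    semantic_map: object
    strengths: pd.DataFrame
    out_dir: Path
    manifest: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "generate":
        params = config.cohort
        if config.seed is not None:
            from dataclasses import replace

            params = replace(params, seed=config.seed)
        records = generate_cohort(params)
        use_stored = False
    elif config.mode == "fixture":
        records = make_fixture_cohort().records
        use_stored = True
    else:
        records = read_cohort_csv(config.csv_path)
        use_stored = True

    write_cohort_csv(records, out / "cohort.csv")
    profiles = derive_profiles(
        records, config.cutoffs, config.mds_cutoff, use_stored_classes=use_stored
    )
    profiles.to_csv(out / "profiles.csv", index=False)

    desc = descriptives_table(profiles)
    desc.to_csv(out / "descriptives.csv", index=False)
    tables = count_tables(profiles)
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    correlations = correlation_table(profiles)
    correlations.to_csv(out / "correlations.csv", index=False)

    dataset = encode_variables(profiles, age_cutoff=config.age_cutoff)
    model = train_autocm(
        dataset,
        C=config.autocm.C,
        lr=config.autocm.lr,
        max_epochs=config.autocm.max_epochs,
        tol=config.autocm.tol,
    )
    strengths = strengths_frame(model)
    strengths.to_csv(out / "strengths.csv")
    smap = build_semantic_map(dataset.variable_names, strengths.to_numpy())
    for fmt, fname in (("tsv", "map_edges.tsv"), ("graphml", "map.graphml"),
                       ("dot", "map.dot")):
        export_map(smap, out / fname, fmt=fmt)

    manifest = {
        "package": "olfmap",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "mode": config.mode,
        "n_records": len(records),
        "n_retained": len(profiles),
        "config": _config_dict(config),
        "autocm": {
            "epochs_run": model.epochs_run,
            "converged": model.converged,
            "C": model.C,
        },
        "map": {
            "hubs": smap.hubs,
            "central_node": smap.central_node,
            "energy": smap.energy,
            "total_distance": smap.total_distance,
        },
        "artifacts": {
            "cohort.csv": "write_cohort_csv",
            "profiles.csv": "derive_profiles",
            "descriptives.csv": "descriptives_table/mean_se",
            "bmi_by_sex.csv": "count_tables/compute_bmi",
            "conditions_by_sex.csv": "count_tables/classify_idf_flags+classify_mets+score_mds",
            "olfactory_status.csv": "count_tables/classify_olfactory",
            "olfactory_by_sex.csv": "count_tables/chi_square_2x2+fisher_exact_2x2",
            "correlations.csv": "correlation_table/pearson_r",
            "strengths.csv": "train_autocm/connection_strengths",
            "map_edges.tsv": "build_semantic_map/export_map",
            "map.graphml": "export_map",
            "map.dot": "export_map",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunResult(
        config=config,
        records=records,
        profiles=profiles,
        tables=tables,
        correlations=correlations,
        semantic_map=smap,
        strengths=strengths,
        out_dir=out,
        manifest=manifest,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
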