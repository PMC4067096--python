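"""Readers, writers, configuration and the end-to-end pipeline.

File conventions
----------------
* All tabular files are tab-separated with a header row; the missing code
  is the literal string ``NA`` (never a numeric sentinel).
* Dosage matrices: first column ``individual``, remaining columns one rsID
  each, values in [0, 2] or NA; a sidecar allele map (two columns
  ``rsid`` / ``counted_allele``) records which allele each column counts.
* VCF input: dosages are taken from the per-genotype ``DS`` field with the
  counted allele equal to ALT; multiallelic records are skipped with a
  warning.
* rsID is the join key everywhere; chromosome/position are annotation.

``run_pipeline`` ties the stages together in analysis order (QC -> scores
-> deseasonalized serum -> association suite) and emits the report tables
with a run-metadata header plus a RunLog.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    combine_freckles,
    combine_sunburn,
    quartile_bins,
    run_paper_suite,
    total_mole_count,
)
from .exceptions import SchemaError, ValidationError
from .scores import (
    DosageMatrix,
    QcThresholds,
    compute_all_scores,
    load_score_definitions,
    qc_snps,
)
from .seasonal import deseasonalize, total_25ohd

logger = logging.getLogger("pigmentscore")

MISSING_CODE = "NA"


# ---------------------------------------------------------------------------
# Dosage I/O
# ---------------------------------------------------------------------------

def read_allele_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"rsid", "counted_allele"} <= set(table.columns):
        raise ValidationError(f"allele map {path} needs columns rsid, counted_allele")
    return dict(zip(table["rsid"], table["counted_allele"]))


def read_dosage_table(path, allele_map) -> DosageMatrix:
    """Tab-separated dosage matrix (individuals x rsIDs, NA for missing)."""
    if not isinstance(allele_map, dict):
        allele_map = read_allele_map(allele_map)
    table = pd.read_csv(path, sep="\t", na_values=[MISSING_CODE], keep_default_na=False)
    first = table.columns[0]
    table = table.set_index(first)
    table.index.name = "individual"
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric dosage value ({exc})") from exc
    values = table.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (values < 0) | (values > 2)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: dosage {values[i, j]} out of [0, 2] at row "
            f"{table.index[i]!r}, column {table.columns[j]!r}"
        )
    unknown = sorted(set(allele_map) - set(table.columns))
    if unknown:
        warnings.warn(
            f"allele map lists rsids absent from {path}: {', '.join(unknown)}",
            stacklevel=2,
        )
    absent = [c for c in table.columns if c not in allele_map]
    if absent:
        raise ValidationError(
            f"{path}: no counted allele for columns {', '.join(absent)}"
        )
    return DosageMatrix(table, allele_map)


def write_dosage_table(dosages: DosageMatrix, path, allele_map_path=None) -> None:
    frame = dosages.dosages.copy()
    frame.index.name = "individual"
    frame.to_csv(path, sep="\t", na_rep=MISSING_CODE)
    if allele_map_path is not None:
        pd.DataFrame(
            {"rsid": list(dosages.counted_allele),
             "counted_allele": list(dosages.counted_allele.values())}
        ).to_csv(allele_map_path, sep="\t", index=False)


def read_vcf_dosages(path) -> DosageMatrix:
    """Dosages from a VCF with the per-genotype ``DS`` field.

    The counted allele is ALT; records are keyed by the ID column rsid.
    Multiallelic records are skipped with a warning; a record without DS is
    a format error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    counted: dict[str, str] = {}
    for record in vcf:
        if len(record.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {record.ID or record.POS}", stacklevel=2
            )
            continue
        ds = record.format("DS")
        if ds is None:
            raise ValidationError(
                f"record {record.ID or record.POS}: no DS (dosage) field"
            )
        rsid = record.ID or f"{record.CHROM}:{record.POS}"
        values = np.asarray(ds, dtype=float).reshape(-1)
        values = np.where((values < 0) | (values > 2), np.nan, values)
        columns[rsid] = values
        counted[rsid] = record.ALT[0]
    frame = pd.DataFrame(columns, index=pd.Index(individuals, name="individual"))
    return DosageMatrix(frame, counted)


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------

def read_phenotypes(path, date_columns=("draw_date",)) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", na_values=[MISSING_CODE], keep_default_na=False, index_col=0
    )
    for c in date_columns:
        if c in table.columns:
            table[c] = pd.to_datetime(table[c])
    return table


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", na_rep=MISSING_CODE)


# ---------------------------------------------------------------------------
# Pipeline configuration and run log
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and settings for one end-to-end run."""

    dosages: str
    phenotypes: str
    allele_map: str | None = None
    score_definitions: str | None = None   # packaged default when None
    out_prefix: str = "pigmentscore_run"
    seed: int = 0
    qc_min_maf: float = 0.01
    qc_min_call_rate: float = 0.95
    qc_min_hwe_p: float = 5e-7
    cosinor_period: float = 365.25
    cosinor_harmonics: int = 1
    cosinor_recenter: bool = True
    drop_qc_failures: bool = True
    pcs: tuple = tuple(f"pc{i}" for i in range(1, 11))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        for attr in ("dosages", "phenotypes", "allele_map", "score_definitions"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{attr} file does not exist: {value}")
        for attr in ("qc_min_maf", "qc_min_call_rate", "qc_min_hwe_p"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValidationError(f"{attr} must lie in [0, 1], got {v}")

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunLog:
    config_hash: str
    seed: int
    version: str = __version__
    events: list = field(default_factory=list)

    def log(self, stage: str, message: str, n: int | None = None) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.events.append({"time": stamp, "stage": stage, "message": message, "n": n})
        logger.info("[%s] %s%s", stage, message, f" (n={n})" if n is not None else "")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)


@dataclass
class ReportBundle:
    tables: dict
    seasonal_params: dict
    runlog: RunLog


def _metadata_header(config: PipelineConfig, n: int | None = None) -> str:
    parts = [f"seed={config.seed}", f"config_hash={config.config_hash()}",
             f"version={__version__}"]
    if n is not None:
        parts.append(f"n={n}")
    return "# " + " ".join(parts) + "\n# quartile ties assigned to the lower bin\n"


def write_table(frame: pd.DataFrame, path, config: PipelineConfig, n=None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(config, n))
        frame.to_csv(fh, sep="\t", na_rep=MISSING_CODE)


def derive_variables(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Combined freckles/sunburn, mole quartiles and total mole count."""
    out = phenotypes.copy()
    if {"freckles_49m", "freckles_61m"} <= set(out.columns):
        out["any_freckles"] = combine_freckles(out["freckles_49m"], out["freckles_61m"])
    sweep_cols = [c for c in out.columns if c.startswith("sunburn_")]
    if len(sweep_cols) == 6:
        out["badly_burnt"] = combine_sunburn(out[sweep_cols])
    if {"mole_arms_186m", "mole_legs_186m"} <= set(out.columns):
        out["mole_count_186m"] = total_mole_count(
            out["mole_arms_186m"], out["mole_legs_186m"]
        )
    for age in ("49m", "61m", "186m"):
        column = f"mole_count_{age}"
        if column in out.columns and out[column].notna().sum() >= 4:
            labels, _ = quartile_bins(out[column])
            out[f"mole_quartile_{age}"] = labels
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """QC -> scores -> deseasonalized serum -> association suite."""
    config.validate()
    runlog = RunLog(config_hash=config.config_hash(), seed=config.seed)

    definitions = load_score_definitions(config.score_definitions)
    runlog.log("definitions", f"loaded {len(definitions)} score definitions")

    if str(config.dosages).endswith((".vcf", ".vcf.gz")):
        dosages = read_vcf_dosages(config.dosages)
    else:
        if config.allele_map is None:
            raise ValidationError("tab-separated dosages require an allele_map")
        dosages = read_dosage_table(config.dosages, config.allele_map)
    runlog.log("dosages", f"{len(dosages.individuals)} individuals, "
               f"{len(dosages.snps)} SNPs", n=len(dosages.individuals))

    thresholds = QcThresholds(
        min_maf=config.qc_min_maf,
        min_call_rate=config.qc_min_call_rate,
        min_hwe_p=config.qc_min_hwe_p,
    )
    qc_report = qc_snps(dosages, thresholds)
    n_fail = int((~qc_report["qc_pass"]).sum())
    runlog.log("qc", f"{n_fail} SNP(s) failed QC", n=len(qc_report))
    if config.drop_qc_failures and n_fail:
        keep = qc_report.index[qc_report["qc_pass"]].tolist()
        dosages = dosages.subset(keep)
        runlog.log("qc", f"dropped {n_fail} failing SNP(s)")

    score_table = compute_all_scores(dosages, definitions)
    for name in score_table.columns:
        runlog.log("scores", f"computed {name}", n=int(score_table[name].notna().sum()))

    phenotypes = read_phenotypes(config.phenotypes)
    serum_needed = {"d3", "d2", "draw_date"}
    missing = sorted(serum_needed - set(phenotypes.columns))
    if missing:
        raise SchemaError(missing)
    phenotypes["total_25ohd"] = total_25ohd(
        phenotypes["d3"].fillna(np.nan), phenotypes["d2"].fillna(np.nan)
    )
    habitual, model = deseasonalize(
        phenotypes,
        period=config.cosinor_period,
        harmonics=config.cosinor_harmonics,
        recenter=config.cosinor_recenter,
    )
    phenotypes["deseasonalized_25ohd"] = habitual
    seasonal_params = {
        "mesor": model.mesor,
        "amplitude": model.amplitude,
        "acrophase_day": model.acrophase,
        "r_squared": model.r_squared,
        "period": model.period,
        "epoch": str(model.epoch.date()),
    }
    runlog.log("deseason", f"cosinor amplitude {model.amplitude:.2f} nmol/l, "
               f"peak day {model.acrophase:.0f}", n=int(habitual.notna().sum()))

    phenotypes = derive_variables(phenotypes)
    tables = run_paper_suite(phenotypes, score_table, pcs=config.pcs)
    for name, table in tables.items():
        runlog.log("assoc", f"table {name}", n=len(table))
    return ReportBundle(tables=tables, seasonal_params=seasonal_params, runlog=runlog)


def write_report_bundle(bundle: ReportBundle, config: PipelineConfig) -> list[Path]:
    """Write every report table plus the seasonal parameters and run log."""
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables.items():
        path = Path(f"{prefix}_{name}.tsv")
        write_table(table, path, config, n=len(table))
        written.append(path)
    params = Path(f"{prefix}_seasonal_model.tsv")
    pd.Series(bundle.seasonal_params).rename("value").to_csv(
        params, sep="\t", header=True
    )
    written.append(params)
    log_path = Path(f"{prefix}_runlog.tsv")
    bundle.runlog.to_frame().to_csv(log_path, sep="\t", index=False, na_rep=MISSING_CODE)
    written.append(log_path)
    return written
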