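"""Pigmentation allele scores from genotype dosages.

Three unweighted genetic scores proxy pigmentation phenotypes in Europeans:
a skin-colour score (6 SNPs), a tanning score (13 SNPs) and a freckling
score (8 SNPs).  Each score is the per-individual sum of expected "risk"
allele counts (dosages in [0, 2]) over its SNP set, where the risk allele is
the one associated with lighter skin, burning rather than tanning, or
freckling.  A SNP may belong to several scores, possibly with *different*
risk alleles (TYR rs1042602: A for skin colour, C for freckling), so dosage
orientation is always performed per (score, SNP) pair.

The module also provides the per-SNP quality-control report (minor-allele
frequency, call rate, Hardy-Weinberg equilibrium) applied before scoring,
and the population-stratification-adjusted inter-score correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlleleMismatchError,
    InsufficientDataError,
    MissingSnpError,
    ScoreDefinitionError,
    ValidationError,
)

NUCLEOTIDES = frozenset("ACGT")
#: Strand-ambiguous allele pairs (indistinguishable under strand flips).
AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

SCORE_NAMES = ("skin_colour", "tanning", "freckling")


@dataclass(frozen=True)
class SnpDefinition:
    """One SNP row of a score definition.

    ``position`` is 1-based and build-specific; it is carried as annotation
    only — rsID is the join key everywhere.
    """

    rsid: str
    gene: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    risk_allele: str

    def __post_init__(self) -> None:
        for name in ("major_allele", "minor_allele", "risk_allele"):
            allele = getattr(self, name)
            if allele not in NUCLEOTIDES:
                raise ScoreDefinitionError(
                    f"{self.rsid}: {name} {allele!r} is not a single nucleotide"
                )
        if self.risk_allele not in (self.major_allele, self.minor_allele):
            raise ScoreDefinitionError(
                f"{self.rsid}: risk allele {self.risk_allele} is neither the "
                f"major ({self.major_allele}) nor the minor ({self.minor_allele}) allele"
            )

    @property
    def other_allele(self) -> str:
        """The non-risk allele."""
        return self.minor_allele if self.risk_allele == self.major_allele else self.major_allele

    @property
    def strand_ambiguous(self) -> bool:
        return frozenset((self.major_allele, self.minor_allele)) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class ScoreDefinition:
    """A named, ordered set of SNPs with score-specific risk alleles."""

    name: str
    snps: tuple[SnpDefinition, ...]

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ScoreDefinitionError(
                f"score {self.name!r}: duplicate rsids {', '.join(dupes)}"
            )

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def max_value(self) -> float:
        return 2.0 * self.n_snps

    def snp(self, rsid: str) -> SnpDefinition:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)


class DosageMatrix:
    """Individuals x SNPs expected allele counts in [0, 2].

    ``dosages`` is a float DataFrame (rows: individual IDs, columns: rsIDs)
    with NaN marking missing genotypes; ``counted_allele`` records, per SNP,
    which allele the dosage counts.
    """

    def __init__(self, dosages: pd.DataFrame, counted_allele: Mapping[str, str]):
        dosages = dosages.astype(float)
        values = dosages.to_numpy()
        with np.errstate(invalid="ignore"):
            out_of_range = (values < 0) | (values > 2)
        if np.any(out_of_range):
            i, j = np.argwhere(out_of_range)[0]
            raise ValidationError(
                f"dosage {values[i, j]!r} out of [0, 2] at individual "
                f"{dosages.index[i]!r}, SNP {dosages.columns[j]!r}"
            )
        missing_alleles = [c for c in dosages.columns if c not in counted_allele]
        if missing_alleles:
            raise ValidationError(
                f"no counted allele recorded for: {', '.join(map(str, missing_alleles))}"
            )
        self.dosages = dosages
        self.counted_allele = {c: counted_allele[c] for c in dosages.columns}

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def missing(self) -> pd.DataFrame:
        return self.dosages.isna()

    def subset(self, rsids: Sequence[str]) -> "DosageMatrix":
        absent = [r for r in rsids if r not in self.dosages.columns]
        if absent:
            raise MissingSnpError(absent)
        return DosageMatrix(self.dosages[list(rsids)], self.counted_allele)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DosageMatrix({self.dosages.shape[0]} individuals x "
            f"{self.dosages.shape[1]} SNPs)"
        )


def load_score_definitions(path=None) -> list[ScoreDefinition]:
    """Load score definitions from a tab-separated file.

    Columns: ``score gene rsid chromosome position major minor risk``.  The
    packaged default reproduces the published three-score composition
    (skin_colour: 6 SNPs, tanning: 13, freckling: 8).  Strand-ambiguous
    (A/T, G/C) SNPs trigger a warning but are trusted as stated.
    """
    if path is None:
        ref = resources.files("pigmentscore.data") / "score_definitions.tsv"
        with resources.as_file(ref) as p:
            return load_score_definitions(p)

    required = ["score", "gene", "rsid", "chromosome", "position", "major", "minor", "risk"]
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ScoreDefinitionError(f"cannot parse score-definition file {path}: {exc}") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ScoreDefinitionError(
            f"score-definition file {path} lacks columns: {', '.join(missing)}"
        )

    definitions: list[ScoreDefinition] = []
    for name, group in table.groupby("score", sort=False):
        snps = []
        for line_no, row in group.iterrows():
            try:
                snp = SnpDefinition(
                    rsid=row["rsid"],
                    gene=row["gene"],
                    chromosome=row["chromosome"],
                    position=int(row["position"]),
                    major_allele=row["major"],
                    minor_allele=row["minor"],
                    risk_allele=row["risk"],
                )
            except (TypeError, ValueError) as exc:
                raise ScoreDefinitionError(
                    f"{path}, data row {line_no + 2}: {exc}"
                ) from exc
            if snp.strand_ambiguous:
                warnings.warn(
                    f"{snp.rsid} ({snp.major_allele}/{snp.minor_allele}) is strand-"
                    "ambiguous; trusting the stated alleles",
                    stacklevel=2,
                )
            snps.append(snp)
        definitions.append(ScoreDefinition(name=str(name), snps=tuple(snps)))
    return definitions


def get_score(definitions: Iterable[ScoreDefinition], name: str) -> ScoreDefinition:
    for d in definitions:
        if d.name == name:
            return d
    raise KeyError(name)


def orient_dosages(raw: DosageMatrix, score: ScoreDefinition) -> DosageMatrix:
    """Re-express dosages as expected *risk-allele* counts for one score.

    Columns counting the risk allele pass through unchanged; columns counting
    the other allele are reflected (d -> 2 - d).  Missing stays missing.  The
    returned matrix is restricted to the score's SNPs, in score order.
    """
    sub = raw.subset(score.rsids)
    oriented = sub.dosages.copy()
    counted = {}
    for snp in score.snps:
        col_allele = sub.counted_allele[snp.rsid]
        if col_allele == snp.risk_allele:
            pass
        elif col_allele == snp.other_allele:
            oriented[snp.rsid] = 2.0 - oriented[snp.rsid]
        else:
            raise AlleleMismatchError(
                f"{snp.rsid}: counted allele {col_allele!r} matches neither "
                f"{snp.major_allele} nor {snp.minor_allele}"
            )
        counted[snp.rsid] = snp.risk_allele
    return DosageMatrix(oriented, counted)


def compute_score(oriented: DosageMatrix, score: ScoreDefinition) -> pd.Series:
    """Sum risk-allele dosages over the score's SNPs.

    Individuals with any missing constituent dosage are excluded (strict
    complete-SNP rule; no imputation).  Returns a float Series named after
    the score, indexed by the retained individuals.
    """
    sub = oriented.subset(score.rsids)
    for rsid in score.rsids:
        if sub.counted_allele[rsid] != score.snp(rsid).risk_allele:
            raise ValidationError(
                f"{rsid}: dosages are not oriented to the {score.name} risk allele; "
                "call orient_dosages first"
            )
    complete = sub.dosages.dropna(axis=0, how="any")
    if complete.empty:
        warnings.warn(
            f"score {score.name}: no individual has complete dosages", stacklevel=2
        )
    return complete.sum(axis=1).rename(score.name)


def compute_all_scores(raw: DosageMatrix, definitions: Iterable[ScoreDefinition]) -> pd.DataFrame:
    """Orient and sum every score; NaN where an individual is incomplete."""
    columns = {}
    for definition in definitions:
        vec = compute_score(orient_dosages(raw, definition), definition)
        columns[definition.name] = vec.reindex(raw.individuals)
    return pd.DataFrame(columns, index=raw.individuals)


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    p_value: float
    monomorphic: bool = False


def hwe_test(genotype_counts: Sequence[int]) -> HweResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` is (hom_major, het, hom_minor).  The allele frequency
    is estimated from the sample and observed counts are compared with the
    p^2, 2pq, q^2 expectations.  A monomorphic sample returns statistic 0,
    p-value 1 and the monomorphic flag.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,):
        raise ValidationError("genotype_counts must be (hom_major, het, hom_minor)")
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise ValidationError("genotype counts must be non-negative integers")
    n = counts.sum()
    if n == 0:
        raise ValidationError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(0.0, 1.0, monomorphic=True)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)))


@dataclass
class QcThresholds:
    """Per-SNP exclusion thresholds (defaults as published)."""

    min_maf: float = 0.01
    min_call_rate: float = 0.95
    min_hwe_p: float = 5e-7

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "min_hwe_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


def qc_snps(dosages: DosageMatrix, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-SNP QC report: MAF, call rate, HWE, pass/fail flags.

    MAF comes from the mean dosage / 2 (folded to the minor side); the HWE
    test uses best-guess genotypes (dosages rounded to the nearest integer).
    Report only — filtering is the caller's choice.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if dosages.dosages.empty:
        raise ValidationError("dosage matrix is empty")

    rows = []
    for rsid in dosages.snps:
        col = dosages.dosages[rsid]
        observed = col.dropna()
        call_rate = len(observed) / len(col)
        counted_freq = observed.mean() / 2.0 if len(observed) else np.nan
        maf = min(counted_freq, 1 - counted_freq) if len(observed) else np.nan
        hard = np.rint(observed.to_numpy()).astype(int)
        genotype_counts = [int((hard == 2 - g).sum()) for g in (2, 1, 0)]
        # counts keyed as (hom in counted allele = 0 copies?, ...): order them
        # (hom other, het, hom counted) so the chi-square is allele-symmetric.
        if len(observed):
            hwe = hwe_test(genotype_counts)
        else:
            hwe = HweResult(np.nan, np.nan, monomorphic=False)
        fail_reasons = []
        if not np.isnan(maf) and maf < thresholds.min_maf:
            fail_reasons.append("maf")
        if call_rate < thresholds.min_call_rate:
            fail_reasons.append("call_rate")
        if not np.isnan(hwe.p_value) and not hwe.monomorphic and hwe.p_value < thresholds.min_hwe_p:
            fail_reasons.append("hwe")
        rows.append(
            {
                "rsid": rsid,
                "counted_allele": dosages.counted_allele[rsid],
                "counted_freq": counted_freq,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_chi_square": hwe.chi_square,
                "hwe_p": hwe.p_value,
                "monomorphic": hwe.monomorphic,
                "qc_pass": not fail_reasons,
                "fail_reasons": ",".join(fail_reasons),
            }
        )
    return pd.DataFrame(rows).set_index("rsid")


def score_correlations(scores: pd.DataFrame, pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise squared Pearson correlations of PC-residualized scores.

    Each score column is residualized on the principal-component columns by
    ordinary least squares over the intersection of complete cases, then the
    squared correlation of residuals is tabulated.  With ``pcs=None`` (or
    all-zero PC columns) this is the raw squared correlation.
    """
    if scores.shape[1] < 2:
        raise ValidationError("need at least two scores")
    frame = scores.copy()
    if pcs is not None:
        pcs = pcs.reindex(frame.index)
        frame = pd.concat([frame, pcs], axis=1)
    complete = frame.dropna(axis=0, how="any")
    if len(complete) < 3:
        raise InsufficientDataError(
            f"only {len(complete)} overlapping complete cases; need at least 3"
        )
    y = complete[scores.columns].to_numpy(dtype=float)
    if pcs is not None and pcs.shape[1]:
        x = np.column_stack([np.ones(len(complete)), complete[pcs.columns].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
    else:
        resid = y - y.mean(axis=0)
    corr = np.corrcoef(resid, rowvar=False)
    return pd.DataFrame(corr**2, index=scores.columns, columns=scores.columns)
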