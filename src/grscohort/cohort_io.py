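"""Reading, validation and writing of cohort inputs and result tables.

Three in-memory containers are shared by every analysis stage:

``SNPPanel``
    The candidate-SNP list. Each record carries the risk allele and the
    published odds ratio whose natural log is the GRS weight. The panel is
    the single source of risk-allele orientation; genotype files never
    override it.

``GenotypeMatrix``
    Samples × SNPs risk-allele dosages in {0, 1, 2}, with ``NaN`` for a
    missing genotype call.

``PhenotypeTable``
    Per-sample case/control status, the case subtype (non-permanent or
    permanent AF), and clinical covariates.

Supported file formats: TSV/CSV for the panel, phenotypes and dosage matrix
(samples as rows, rsIDs as columns, ``NA`` for missing), and VCF v4.x
(GT field only) for genotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SNPPanelRecord",
    "SNPPanel",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_tables",
]

#: Sentinel for a missing genotype call (stored as NaN in float matrices).
MISSING = float("nan")

_VALID_ALLELES = frozenset("ACGT")

CASE = "case"
CONTROL = "control"
SUBTYPE_NONE = "none"
SUBTYPE_NONPERM = "non-permanent"
SUBTYPE_PERM = "permanent"

#: Canonical analysis group labels.
GROUP_AF = "AF"
GROUP_NAF = "NAF"
GROUP_NP_AF = "NP-AF"
GROUP_P_AF = "P-AF"

#: Optional covariate columns recognised in a phenotype table.
COVARIATE_COLUMNS = (
    "sex_male",
    "age",
    "bmi",
    "ever_smoker",
    "diuresis",
    "cad",
    "mi",
    "hypertrophy",
)


@dataclass(frozen=True)
class SNPPanelRecord:
    """One candidate SNP: identity, risk allele and published-OR weight."""

    rsid: str
    gene: str
    risk_allele: str
    or_published: float
    weight: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: risk allele must be one of A/C/G/T, got {self.risk_allele!r}"
            )
        if not (self.or_published > 0 and math.isfinite(self.or_published)):
            raise ValueError(
                f"{self.rsid}: published OR must be a positive finite number, "
                f"got {self.or_published!r}"
            )
        if abs(self.weight - math.log(self.or_published)) > 1e-12:
            raise ValueError(f"{self.rsid}: weight must equal ln(or_published)")


def make_panel_record(
    rsid: str, gene: str, risk_allele: str, or_published: float, source: str = ""
) -> SNPPanelRecord:
    """Build a record with the weight derived as ln(published OR)."""
    or_published = float(or_published)
    if not (or_published > 0 and math.isfinite(or_published)):
        raise ValueError(
            f"{rsid}: published OR must be a positive finite number, got {or_published!r}"
        )
    return SNPPanelRecord(
        rsid=str(rsid),
        gene=str(gene),
        risk_allele=str(risk_allele).upper(),
        or_published=float(or_published),
        weight=math.log(float(or_published)),
        source=str(source),
    )


class SNPPanel:
    """Ordered collection of :class:`SNPPanelRecord` with unique rsIDs."""

    def __init__(self, records: Iterable[SNPPanelRecord]):
        self.records: list[SNPPanelRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValueError(f"duplicate rsid in panel: {rec.rsid}")
            seen.add(rec.rsid)
        self._by_rsid = {rec.rsid: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SNPPanelRecord]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def get(self, rsid: str) -> SNPPanelRecord:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise KeyError(f"rsid {rsid} not in panel") from None

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    @property
    def weights(self) -> dict[str, float]:
        """rsid → ln(published OR), the per-allele GRS weight."""
        return {rec.rsid: rec.weight for rec in self.records}

    @property
    def risk_alleles(self) -> dict[str, str]:
        return {rec.rsid: rec.risk_allele for rec in self.records}

    def subset(self, rsids: Iterable[str]) -> "SNPPanel":
        return SNPPanel(self.get(r) for r in rsids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "gene": [r.gene for r in self.records],
                "risk_allele": [r.risk_allele for r in self.records],
                "or_published": [r.or_published for r in self.records],
                "weight": [r.weight for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


class GenotypeMatrix:
    """Risk-allele dosage matrix: samples as rows, SNPs as columns.

    Values are floats in {0, 1, 2} counting copies of the panel risk allele,
    with NaN marking a missing genotype call.
    """

    def __init__(self, dosage: pd.DataFrame):
        dosage = dosage.astype(float)
        values = dosage.to_numpy()
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad[:5]!r}")
        if dosage.index.has_duplicates:
            raise ValueError("duplicate sample ids in genotype matrix")
        if dosage.columns.has_duplicates:
            raise ValueError("duplicate snp ids in genotype matrix")
        self.dosage = dosage

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def column(self, rsid: str) -> pd.Series:
        if rsid not in self.dosage.columns:
            raise KeyError(f"rsid {rsid} not in genotype matrix")
        return self.dosage[rsid]

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(sample_ids)])


class PhenotypeTable:
    """Per-sample AF status, case subtype and clinical covariates.

    The underlying frame is indexed by sample id. ``af_status`` holds
    ``case``/``control``; ``af_subtype`` holds ``none`` for every control and
    ``non-permanent``/``permanent`` (or missing) for cases.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        if "af_status" not in frame.columns:
            raise ValueError("phenotype table must contain an af_status column")
        status = frame["af_status"]
        unknown = set(status.dropna().unique()) - {CASE, CONTROL}
        if unknown:
            raise ValueError(f"unknown af_status levels: {sorted(unknown)}")
        if status.isna().any():
            raise ValueError("af_status may not be missing")
        if len(set(status)) != 2:
            raise ValueError("phenotype table must contain both cases and controls")
        if "af_subtype" not in frame.columns:
            frame = frame.copy()
            frame["af_subtype"] = np.where(status == CONTROL, SUBTYPE_NONE, np.nan)
        subtype = frame["af_subtype"]
        bad_levels = set(subtype.dropna().unique()) - {
            SUBTYPE_NONE,
            SUBTYPE_NONPERM,
            SUBTYPE_PERM,
        }
        if bad_levels:
            raise ValueError(f"unknown af_subtype levels: {sorted(bad_levels)}")
        ctrl = status == CONTROL
        if (subtype[ctrl] != SUBTYPE_NONE).any():
            raise ValueError("controls must have af_subtype 'none'")
        if (subtype[~ctrl] == SUBTYPE_NONE).any():
            raise ValueError("cases may not have af_subtype 'none'")
        self.frame = frame

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["af_status"] == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["af_status"] == CONTROL])

    def group_ids(self, group: str) -> list[str]:
        """Sample ids of an analysis group: AF, NAF, NP-AF or P-AF."""
        key = group.strip().upper().replace("_", "-")
        if key == GROUP_AF:
            return self.case_ids
        if key == GROUP_NAF:
            return self.control_ids
        if key in (GROUP_NP_AF, "NON-PERMANENT"):
            sel = self.frame["af_subtype"] == SUBTYPE_NONPERM
            return list(self.frame.index[sel])
        if key in (GROUP_P_AF, "PERMANENT"):
            sel = self.frame["af_subtype"] == SUBTYPE_PERM
            return list(self.frame.index[sel])
        raise ValueError(f"unknown group {group!r}; expected AF, NAF, NP-AF or P-AF")

    def covariates(self, names: Iterable[str]) -> pd.DataFrame:
        names = list(names)
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"covariates absent from phenotype table: {missing}")
        return self.frame[names].astype(float)


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, na_values=["NA", ""])


def read_panel(path: str | Path) -> SNPPanel:
    """Read a SNP panel from a TSV/CSV with columns rsid, gene, risk_allele,
    or_published and (optionally) source. Weights are computed as
    ln(or_published); malformed rows raise ``ValueError``.
    """
    df = _read_table(path)
    required = {"rsid", "gene", "risk_allele", "or_published"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            or_pub = float(row["or_published"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{row['rsid']}: or_published is not numeric: {row['or_published']!r}"
            ) from None
        records.append(
            make_panel_record(
                rsid=row["rsid"],
                gene=row["gene"],
                risk_allele=row["risk_allele"],
                or_published=or_pub,
                source=row.get("source", "") if isinstance(row.get("source"), str) else "",
            )
        )
    return SNPPanel(records)


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    """Read a wide dosage TSV (samples as rows, rsIDs as columns, NA missing).

    By convention the TSV counts copies of the panel risk allele, so no
    orientation flip is applied. Panel SNPs absent from the file become
    all-missing columns (with a warning); columns not in the panel are
    ignored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    cols = {}
    for rsid in panel.rsids:
        if rsid in df.columns:
            cols[rsid] = df[rsid].astype(float)
        else:
            warnings.warn(f"panel SNP {rsid} absent from {path}; recorded as all-missing")
            cols[rsid] = pd.Series(np.nan, index=df.index)
    return GenotypeMatrix(pd.DataFrame(cols, index=df.index))


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as TSV with NA for missing (round-trips exactly)."""
    out = matrix.dosage.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _vcf_dosages(path: str | Path, panel: SNPPanel) -> dict[str, tuple[list[str], list[float]]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    seen: dict[str, list[float]] = {}
    wanted = set(panel.rsids)
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in wanted:
            continue
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            raise ValueError(f"{rsid}: only biallelic SNVs are supported")
        risk = panel.get(rsid).risk_allele
        ref, alt = variant.REF, variant.ALT[0]
        if risk == alt:
            flip = False
        elif risk == ref:
            flip = True
        else:
            raise ValueError(
                f"{rsid}: panel risk allele {risk} matches neither REF ({ref}) nor ALT ({alt})"
            )
        dosages: list[float] = []
        for gt in variant.genotypes:
            alleles = gt[:-1]
            # half-calls (./1) are treated as missing, conservatively
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                dosages.append(np.nan)
                continue
            alt_count = float(sum(1 for a in alleles if a == 1))
            dosages.append(2.0 - alt_count if flip else alt_count)
        seen[rsid] = dosages
    return {rsid: (samples, d) for rsid, d in seen.items()}


def read_genotypes(
    path: str | Path, panel: SNPPanel, format: str = "dosage_tsv"
) -> GenotypeMatrix:
    """Read genotypes from a VCF or wide dosage TSV, oriented to the panel.

    For VCF input only the GT field is used; phased and unphased calls are
    treated identically. When the risk allele is the REF allele, dosages are
    flipped (2 − ALT count) so that the matrix always counts risk alleles.
    A panel SNP absent from the file becomes an all-missing column with a
    warning; a site whose alleles do not include the risk allele is an error.
    """
    if format in ("dosage_tsv", "tsv"):
        return read_dosage_tsv(path, panel)
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}; expected vcf or dosage_tsv")
    found = _vcf_dosages(path, panel)
    if not found:
        raise ValueError(f"no panel SNPs found in {path}")
    samples = next(iter(found.values()))[0]
    cols = {}
    for rsid in panel.rsids:
        if rsid in found:
            cols[rsid] = pd.Series(found[rsid][1], index=samples)
        else:
            warnings.warn(f"panel SNP {rsid} absent from {path}; recorded as all-missing")
            cols[rsid] = pd.Series(np.nan, index=samples)
    return GenotypeMatrix(pd.DataFrame(cols, index=pd.Index(samples, dtype=str)))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype/covariate TSV or CSV.

    Requires ``sample_id`` and ``af_status`` columns; ``af_subtype`` and the
    clinical covariates are optional. Unknown status or subtype levels and
    case/control–subtype inconsistencies raise ``ValueError``.
    """
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError("phenotype file must contain a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for col in COVARIATE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    out = phenotypes.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named result table as ``<name>.tsv`` under ``out_dir``.

    Output is deterministic: re-running with identical inputs produces
    byte-identical files. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths.append(p)
    return paths
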