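"""File formats: subject CSV, dosage TSV, minimal VCF, weight/rate tables.

Dialect: UTF-8; comma-separated CSV and tab-separated TSV; ``.`` for
missing values; mandatory header row.  Every writer accepts a ``meta``
mapping emitted as ``# key: value`` comment lines above the header, which
all paired readers skip, so writer→reader round trips are lossless.

Genotypes interchange either as a dosage TSV (subjects x SNPs, values
0/1/2/.) or as a minimal VCF: GT-only FORMAT, unphased, biallelic records,
one sample column per subject.  Dosages count copies of the *risk* allele
declared in the weight/panel file; when the risk allele is the VCF REF the
GT codes are flipped on read.  Positions are identifiers, never analyzed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .absolute_risk import RateTable, RiskDistribution
from .cohort import SnpSpec
from .errors import AlleleMismatchError, UnsupportedRecordError
from .scores import WeightVector

MISSING = "."


def _write_with_meta(
    frame: pd.DataFrame, path: str | Path, sep: str, meta: Mapping | None, index: bool
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep=sep, na_rep=MISSING, index=index, lineterminator="\n")


def _read_table(path: str | Path, sep: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=sep, comment="#", na_values=[MISSING], keep_default_na=True,
        index_col=index_col, float_precision="round_trip",
    )


# -- subjects ---------------------------------------------------------------

def write_subjects(subjects: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    frame = subjects.copy()
    if "fit_positive" in frame.columns:
        frame["fit_positive"] = frame["fit_positive"].astype(int)
    _write_with_meta(frame, path, ",", meta, index=True)


def read_subjects(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, ",", index_col="subject_id")
    if "fit_positive" in frame.columns:
        frame["fit_positive"] = frame["fit_positive"].astype(bool)
    return frame


# -- genotypes: dosage TSV --------------------------------------------------

def write_dosages(genotypes: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    frame = genotypes.copy()
    # integral dosages; keep "." for missing
    frame = frame.map(lambda v: "" if pd.isna(v) else str(int(v))).replace("", np.nan)
    _write_with_meta(frame, path, "\t", meta, index=True)


def read_dosages(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, "\t", index_col="subject_id")
    return frame.astype(float)


# -- genotypes: minimal VCF -------------------------------------------------

def write_vcf(
    genotypes: pd.DataFrame,
    specs: Sequence[SnpSpec],
    path: str | Path,
    meta: Mapping | None = None,
) -> None:
    """GT-only unphased VCF; one record per SNP, ALT = risk allele.

    Positions are synthetic sequential identifiers on contig ``1``; 1-based
    coordinates are preserved verbatim by the reader and never re-mapped.
    """
    path = Path(path)
    samples = list(genotypes.index)
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=crcrisk {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"##crcrisk_{key}={value}\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for pos, spec in enumerate(specs, start=1):
            col = genotypes[spec.snp_id]
            gts = "\t".join(
                "./." if pd.isna(v) else code[float(v)] for v in col
            )
            fh.write(
                f"1\t{pos * 1000}\t{spec.snp_id}\t{spec.other_allele}\t"
                f"{spec.risk_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | Path, risk_alleles: Mapping[str, str]
) -> tuple[pd.DataFrame, list[SnpSpec]]:
    """Parse a GT-only VCF into a risk-allele dosage table.

    ``risk_alleles`` maps SNP id -> risk allele (typically from the weight
    file); a risk allele matching neither REF nor ALT raises
    :class:`AlleleMismatchError`, a multiallelic record
    :class:`UnsupportedRecordError`.  Returns the dosage table and SnpSpec
    stubs (raf = in-sample risk-allele frequency, weight 0).
    """
    dosage_cols: dict[str, np.ndarray] = {}
    stubs: list[SnpSpec] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise UnsupportedRecordError(
                    f"{rec.id or rec.pos}: only biallelic records are supported"
                )
            ref, alt = rec.ref, rec.alts[0]
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            risk = risk_alleles.get(snp_id)
            if risk is None:
                raise KeyError(f"no risk allele declared for {snp_id}")
            if risk == alt:
                flip = False
            elif risk == ref:
                flip = True
            else:
                raise AlleleMismatchError(
                    f"{snp_id}: risk allele {risk} matches neither REF={ref} nor ALT={alt}"
                )
            col = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = sum(gt)
                col[i] = (len(gt) - alt_count) if flip else alt_count
            dosage_cols[snp_id] = col
            called = col[~np.isnan(col)]
            raf = float(called.mean() / 2) if called.size else 0.5
            raf = min(max(raf, 1e-6), 1 - 1e-6)
            stubs.append(
                SnpSpec(
                    snp_id=snp_id,
                    risk_allele=risk,
                    raf=raf,
                    weight=0.0,
                    other_allele=ref if not flip else alt,
                )
            )
    table = pd.DataFrame(dosage_cols, index=pd.Index(samples, name="subject_id"))
    return table, stubs


# -- SNP panel and weight vectors ------------------------------------------

def write_panel(specs: Sequence[SnpSpec], path: str | Path, meta: Mapping | None = None) -> None:
    frame = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in specs],
            "risk_allele": [s.risk_allele for s in specs],
            "other_allele": [s.other_allele for s in specs],
            "raf": [s.raf for s in specs],
            "weight": [s.weight for s in specs],
            "inbreeding_f": [s.inbreeding_f for s in specs],
        }
    )
    _write_with_meta(frame, path, "\t", meta, index=False)


def read_panel(path: str | Path) -> list[SnpSpec]:
    frame = _read_table(path, "\t")
    return [
        SnpSpec(
            snp_id=str(r.snp_id),
            risk_allele=str(r.risk_allele),
            other_allele=str(r.other_allele),
            raf=float(r.raf),
            weight=float(r.weight),
            inbreeding_f=float(r.inbreeding_f),
        )
        for r in frame.itertuples()
    ]


def write_weights(
    weights: WeightVector,
    path: str | Path,
    risk_alleles: Mapping[str, str] | None = None,
    meta: Mapping | None = None,
) -> None:
    """Weight TSV: columns id, risk_allele (blank for lifestyle), beta."""
    frame = pd.DataFrame(
        {
            "id": list(weights.names),
            "risk_allele": [
                (risk_alleles or {}).get(n, "") for n in weights.names
            ],
            "beta": list(weights.betas),
        }
    )
    _write_with_meta(frame, path, "\t", meta, index=False)


def read_weights(path: str | Path) -> tuple[WeightVector, dict[str, str]]:
    frame = _read_table(path, "\t")
    names = [str(n) for n in frame["id"]]
    vec = WeightVector(tuple(names), tuple(float(b) for b in frame["beta"]))
    alleles = {
        str(r.id): str(r.risk_allele)
        for r in frame.itertuples()
        if isinstance(r.risk_allele, str) and r.risk_allele
    }
    return vec, alleles


# -- rate tables and risk distributions -------------------------------------

def write_rate_table(rates: RateTable, path: str | Path, meta: Mapping | None = None) -> None:
    frame = rates.to_frame()
    frame["incidence_per_100k"] = frame.pop("incidence") * 1e5
    frame["mortality_per_100k"] = frame.pop("mortality") * 1e5
    _write_with_meta(frame, path, ",", meta, index=False)


def read_rate_table(path: str | Path, sex: str | None = None) -> RateTable:
    """Read a per-100,000 person-year rate CSV; internal unit is per year."""
    frame = _read_table(path, ",")
    if sex is not None:
        frame = frame[frame["sex"] == sex]
        if frame.empty:
            raise ValueError(f"no rate rows for sex {sex!r}")
    frame = frame.assign(
        incidence=frame["incidence_per_100k"] / 1e5,
        mortality=frame["mortality_per_100k"] / 1e5,
    )
    return RateTable.from_frame(frame, sex=sex or "")


def write_risk_distribution(
    dist: RiskDistribution, path: str | Path, meta: Mapping | None = None
) -> None:
    _write_with_meta(dist.frame, path, ",", meta, index=False)


def read_risk_distribution(path: str | Path, sex: str | None = None) -> RiskDistribution:
    frame = _read_table(path, ",")
    if sex is not None and "sex" in frame.columns:
        frame = frame[frame["sex"] == sex].reset_index(drop=True)
    return RiskDistribution(frame)


# -- generic result tables --------------------------------------------------

def write_frame(frame: pd.DataFrame, path: str | Path, meta: Mapping | None = None,
                sep: str = ",", index: bool = False) -> None:
    _write_with_meta(frame, path, sep, meta, index=index)


def read_frame(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return _read_table(path, sep)


def config_hash(config_dict: Mapping) -> str:
    """Short stable hash of a configuration mapping (for output headers)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
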