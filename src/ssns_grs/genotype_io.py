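"""Genotype input/output, variant QC and allele harmonisation.

Genotypes arrive either as VCF (sequenced or imputed, read through pysam)
or as the five-SNP tabular dosage dialect used for assayed cohorts
(header ``sample_id`` then one column per rsID holding the counted-allele
dosage). Variant-level QC mirrors the source study's filters: sequenced
data keep biallelic sites with per-genotype GQ > 20 and DP > 10 and
per-variant overall pass rate (OPR) > 0.8; imputed data keep biallelic
sites with call rate > 95% and imputation Rsq > 0.8. All inequalities are
strict.

Harmonisation maps each model locus onto the matrix and converts ALT
dosages into counted-allele counts: the effect-allele dosage is flipped
(2 - d) when the effect allele is the REF, strand-flipped non-ambiguous
SNPs are complement-matched, and protective loci count the non-effect
allele. A/T and C/G sites are strand-ambiguous and rejected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import (
    AmbiguousStrandError,
    ConfigurationError,
    DomainError,
    MissingLocusError,
    ParseError,
)
from .risk_model import MISSING, RiskModel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "rsq", "opr", "multiallelic"]


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage matrix with QC metadata.

    ``dosages`` is float with NaN for missing calls; entries otherwise in
    {0, 1, 2}. ``variants`` is a DataFrame with one row per variant
    (columns ``chrom, pos, id, ref, alt, rsq, opr, multiallelic``) whose
    row order matches the dosage columns. ``gq``/``dp`` are optional
    per-genotype arrays of the same shape as ``dosages``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    provenance: str = "sequenced"

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise DomainError("dosage matrix shape inconsistent with metadata")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DomainError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
            gq=self.gq[:, mask] if self.gq is not None else None,
            dp=self.dp[:, mask] if self.dp is not None else None,
            provenance=self.provenance,
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(
            sample_ids=list(keep),
            variants=self.variants.copy(),
            dosages=self.dosages[rows],
            gq=self.gq[rows] if self.gq is not None else None,
            dp=self.dp[rows] if self.dp is not None else None,
            provenance=self.provenance,
        )


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-", 1)
    return chrom, int(start), int(end)


def read_vcf(
    path: str | Path,
    region_filter: str | None = None,
    provenance: str = "sequenced",
) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a GenotypeMatrix.

    ALT dosages count copies of the first ALT allele; records with more
    than one ALT are flagged ``multiallelic`` rather than split, and are
    removed by the QC filters. Missing calls (``./.``) become NaN.
    """
    region = _parse_region(region_filter) if region_filter else None
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open VCF: {exc}") from exc
    samples = list(vf.header.samples)
    rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    any_gq = any_dp = False
    try:
        for line_no, rec in enumerate(vf, start=1):
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom:
                    continue
                if start is not None and not (start <= rec.pos <= end):
                    continue
            alts = rec.alts or ()
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "ref": rec.ref,
                    "alt": alts[0] if alts else "",
                    "rsq": float(rec.info["RSQ"]) if "RSQ" in rec.info else np.nan,
                    "opr": float(rec.info["OPR"]) if "OPR" in rec.info else np.nan,
                    "multiallelic": len(alts) > 1,
                }
            )
            dos = np.full(len(samples), np.nan)
            gq = np.full(len(samples), np.nan)
            dp = np.full(len(samples), np.nan)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call["GT"]
                if alleles is not None and None not in alleles:
                    dos[j] = sum(1 for a in alleles if a == 1)
                if call.get("GQ") is not None:
                    gq[j] = call["GQ"]
                    any_gq = True
                if call.get("DP") is not None:
                    dp[j] = call["DP"]
                    any_dp = True
            dosage_cols.append(dos)
            gq_cols.append(gq)
            dp_cols.append(dp)
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"{path}: malformed VCF near record {len(rows) + 1}: {exc}"
        ) from exc

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    n_var = len(variants)
    shape = (len(samples), n_var)
    dosages = (
        np.column_stack(dosage_cols) if n_var else np.empty(shape)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        variants=variants,
        dosages=dosages.reshape(shape),
        gq=np.column_stack(gq_cols).reshape(shape) if any_gq else None,
        dp=np.column_stack(dp_cols).reshape(shape) if any_dp else None,
        provenance=provenance,
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in pd.unique(matrix.variants["chrom"]):
        max_pos = int(matrix.variants.loc[matrix.variants["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=max_pos + 1000)
    header.info.add("RSQ", 1, "Float", "Imputation quality")
    header.info.add("OPR", 1, "Float", "Overall pass rate")
    header.formats.add("GT", 1, "String", "Genotype")
    if matrix.gq is not None:
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
    if matrix.dp is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in matrix.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for k, var in matrix.variants.iterrows():
            rec = out.new_record(
                contig=str(var["chrom"]),
                start=int(var["pos"]) - 1,
                stop=int(var["pos"]),
                alleles=(var["ref"], var["alt"]),
                id=var["id"],
            )
            if not np.isnan(var["rsq"]):
                rec.info["RSQ"] = float(var["rsq"])
            if not np.isnan(var["opr"]):
                rec.info["OPR"] = float(var["opr"])
            for j, s in enumerate(matrix.sample_ids):
                d = matrix.dosages[j, k]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    d = int(d)
                    rec.samples[s]["GT"] = (
                        (0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1)
                    )
                if matrix.gq is not None and not np.isnan(matrix.gq[j, k]):
                    rec.samples[s]["GQ"] = int(matrix.gq[j, k])
                if matrix.dp is not None and not np.isnan(matrix.dp[j, k]):
                    rec.samples[s]["DP"] = int(matrix.dp[j, k])
            out.write(rec)


def read_dosage_tsv(
    path: str | Path, model: RiskModel
) -> tuple[np.ndarray, list[str]]:
    """Read the tabular counted-dosage dialect, aligned to model loci.

    Header: ``sample_id`` then one column per rsID; cells hold the
    counted-allele dosage (0/1/2, empty = missing). Returns the counted
    matrix (MISSING sentinel for empty cells) and the sample ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [m for m in model.marker_ids if m not in df.columns]
    if missing_cols:
        raise MissingLocusError(f"dosage table lacks columns {missing_cols}")
    out = df.set_index("sample_id")[model.marker_ids].to_numpy(dtype=float)
    bad = out[~np.isnan(out)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise ParseError(f"{path}: dosages must be 0, 1, 2 or empty")
    counted = np.where(np.isnan(out), MISSING, out).astype(int)
    return counted, df["sample_id"].tolist()


def write_dosage_tsv(
    counted: np.ndarray,
    sample_ids: Sequence[str],
    model: RiskModel,
    path: str | Path,
) -> None:
    df = pd.DataFrame(counted, columns=model.marker_ids)
    df = df.astype(object).where(df != MISSING, other="")
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def apply_sequencing_qc(
    matrix: GenotypeMatrix,
    gq_min: float | None = 20,
    dp_min: float | None = 10,
    opr_min: float | None = 0.8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sequencing-data QC: per-genotype GQ/DP masking, OPR and biallelic filters.

    Genotypes with GQ <= gq_min or DP <= dp_min (strict thresholds, so a
    genotype at exactly the threshold fails) are set missing; variants
    with OPR <= opr_min or with more than one ALT are removed. Pass None
    to disable a threshold. Returns the filtered matrix and a QC report
    (variant id, filter, reason) for removed variants.
    """
    dosages = matrix.dosages.copy()
    if gq_min is not None:
        if matrix.gq is None:
            raise ConfigurationError("GQ filter requested but no GQ annotations")
        dosages[~(matrix.gq > gq_min)] = np.nan
    if dp_min is not None:
        if matrix.dp is None:
            raise ConfigurationError("DP filter requested but no DP annotations")
        dosages[~(matrix.dp > dp_min)] = np.nan
    masked = replace(matrix, dosages=dosages)

    keep = np.ones(matrix.n_variants, dtype=bool)
    reasons: list[tuple[str, str]] = []
    multi = matrix.variants["multiallelic"].to_numpy(dtype=bool)
    for i in np.flatnonzero(multi):
        reasons.append((matrix.variants.loc[i, "id"], "multiallelic"))
    keep &= ~multi
    if opr_min is not None:
        opr = matrix.variants["opr"].to_numpy(dtype=float)
        if np.isnan(opr).all() and matrix.n_variants:
            raise ConfigurationError("OPR filter requested but no OPR annotations")
        fail = ~(opr > opr_min)
        for i in np.flatnonzero(fail & keep):
            reasons.append((matrix.variants.loc[i, "id"], f"OPR<= {opr_min}"))
        keep &= ~fail
    report = pd.DataFrame(reasons, columns=["variant", "reason"])
    report.insert(1, "filter", "sequencing_qc")
    return masked.subset_variants(keep), report


def apply_imputed_qc(
    matrix: GenotypeMatrix,
    call_rate_min: float | None = 0.95,
    rsq_min: float | None = 0.8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Imputed-data QC: call rate > call_rate_min and Rsq > rsq_min, biallelic.

    Strict inequalities: a variant at exactly the threshold is removed.
    """
    keep = np.ones(matrix.n_variants, dtype=bool)
    reasons: list[tuple[str, str]] = []
    multi = matrix.variants["multiallelic"].to_numpy(dtype=bool)
    for i in np.flatnonzero(multi):
        reasons.append((matrix.variants.loc[i, "id"], "multiallelic"))
    keep &= ~multi
    if call_rate_min is not None:
        fail = ~(matrix.call_rate() > call_rate_min)
        for i in np.flatnonzero(fail & keep):
            reasons.append((matrix.variants.loc[i, "id"], f"call_rate<= {call_rate_min}"))
        keep &= ~fail
    if rsq_min is not None:
        rsq = matrix.variants["rsq"].to_numpy(dtype=float)
        if np.isnan(rsq).all() and matrix.n_variants:
            raise ConfigurationError("Rsq filter requested but no Rsq annotations")
        fail = ~(rsq > rsq_min)
        for i in np.flatnonzero(fail & keep):
            reasons.append((matrix.variants.loc[i, "id"], f"Rsq<= {rsq_min}"))
        keep &= ~fail
    report = pd.DataFrame(reasons, columns=["variant", "reason"])
    report.insert(1, "filter", "imputed_qc")
    return matrix.subset_variants(keep), report


def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def harmonise_to_model(
    matrix: GenotypeMatrix,
    model: RiskModel,
    ambiguous_policy: str = "reject",
    variant_for_locus: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[bool]]:
    """Convert ALT dosages into the model's counted-allele convention.

    For each model locus the variant is located by rsID (or by an explicit
    ``variant_for_locus`` mapping, e.g. from proxy selection — the mapped
    variant then inherits the locus's allele roles). The effect-allele
    dosage is the ALT dosage when effect == ALT, ``2 - ALT`` when
    effect == REF; otherwise the complementary strand is tried for
    non-ambiguous SNPs. Protective loci then count the non-effect allele
    (c = 2 - effect dosage). Strand-ambiguous A/T and C/G sites raise
    under ``ambiguous_policy='reject'``; ``'trust'`` assumes both sources
    report the same strand.

    Returns (counted matrix with MISSING sentinel, per-locus proxy flags).
    """
    if ambiguous_policy not in ("reject", "trust"):
        raise DomainError(f"unknown ambiguous policy {ambiguous_policy!r}")
    by_id = {v: i for i, v in enumerate(matrix.variants["id"])}
    counted = np.full((matrix.n_samples, model.n_loci), MISSING, dtype=int)
    proxy_used: list[bool] = []
    for li, locus in enumerate(model.loci):
        target = locus.marker_id
        is_proxy = False
        if variant_for_locus and locus.marker_id in variant_for_locus:
            target = variant_for_locus[locus.marker_id]
            is_proxy = target != locus.marker_id
        if target not in by_id:
            raise MissingLocusError(
                f"{locus.marker_id}: variant {target} absent from genotype data"
            )
        proxy_used.append(is_proxy)
        col = by_id[target]
        ref = matrix.variants.loc[col, "ref"]
        alt = matrix.variants.loc[col, "alt"]
        ea = locus.effect_allele
        if is_proxy:
            # Proxy alleles need not match the index SNP's; orientation is
            # the caller's responsibility (ld_proxy chooses the proxy allele
            # correlated with the effect allele and reports it as ALT).
            effect_dosage = matrix.dosages[:, col]
        else:
            if _is_ambiguous(ref, alt) and ambiguous_policy == "reject":
                raise AmbiguousStrandError(
                    f"{locus.marker_id}: {ref}/{alt} is strand-ambiguous"
                )
            if ea == alt:
                effect_dosage = matrix.dosages[:, col]
            elif ea == ref:
                effect_dosage = 2.0 - matrix.dosages[:, col]
            elif _COMPLEMENT.get(ea) == alt and not _is_ambiguous(ref, alt):
                effect_dosage = matrix.dosages[:, col]
            elif _COMPLEMENT.get(ea) == ref and not _is_ambiguous(ref, alt):
                effect_dosage = 2.0 - matrix.dosages[:, col]
            else:
                raise MissingLocusError(
                    f"{locus.marker_id}: effect allele {ea} matches neither "
                    f"{ref}/{alt} nor their complements"
                )
        if locus.direction == "protective":
            c = 2.0 - effect_dosage
        else:
            c = effect_dosage
        counted[:, li] = np.where(np.isnan(c), MISSING, c).astype(int)
    return counted, proxy_used


def load_qc_config(path: str | Path) -> dict[str, float]:
    """Parse a flat key=value QC-threshold config (``#`` comments allowed)."""
    out: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: expected key=value, got {raw!r}")
        key, val = (p.strip() for p in line.split("=", 1))
        out[key] = None if val.lower() in ("none", "off") else float(val)
    return out
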