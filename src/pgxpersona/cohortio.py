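"""Readers/writers for the external formats, pipeline configuration and the
end-to-end orchestration simulate -> qc -> pgs -> assoc (-> crosstrait).

Formats
-------
* summary statistics: TSV with header SNP CHR BP A1 A2 BETA SE P N
* genotypes: VCF (one record per variant, FORMAT ``DS`` holding the dosage,
  ``IMPINFO`` carrying the imputation quality) or a dosage TSV (IID column
  plus one column per variant) accompanied by a ``*.variants.tsv`` sidecar
  with the per-variant metadata
* phenotypes: TSV with header IID RESPONSE REMISSION AGE SEX SITE
* gene intervals: 4-column BED (0-based half-open)
* score profiles: TSV with IID plus one SCORE_PT_* column per threshold and
  a YAML sidecar recording M_T counts and parameters

Coordinates are 1-based in VCF and summary statistics and 0-based half-open
in BED; conversion happens at the format boundary.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DataError, DosageMatrix, validate_sumstats
from .genoqc import QcThresholds, apply_qc
from .pgscore import (
    ClumpParams,
    PgsProfile,
    ThresholdGrid,
    clump,
    compute_pgs,
    harmonize_alleles,
    score_column,
)

__all__ = [
    "read_sumstats", "write_sumstats",
    "read_genotypes", "write_genotypes_vcf", "write_genotypes_tsv",
    "read_phenotypes", "write_phenotypes",
    "read_genes_bed", "read_profile", "write_profile",
    "PipelineConfig", "RunManifest", "run_pipeline",
]


# --------------------------------------------------------------------------- #
# summary statistics
def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics table.

    Requires columns SNP, CHR, BP, A1, A2, BETA, P (SE and N optional);
    rejects duplicate SNP ids and p-values outside (0, 1] with the line
    number of the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    if "SNP" not in df.columns:
        raise DataError(f"{path}: missing mandatory column SNP")
    for col in ("CHR", "BP", "A1", "A2", "BETA", "P"):
        if col not in df.columns:
            raise DataError(f"{path}: missing mandatory column {col}")
    for col in ("BP", "BETA", "P") + (("SE",) if "SE" in df else ()) + (("N",) if "N" in df else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise DataError(f"{path}: unparseable {col} value at line {line}")
        df[col] = coerced
    dup = df["SNP"].duplicated()
    if dup.any():
        raise DataError(f"{path}: duplicated SNP id {df['SNP'][dup].iloc[0]!r}")
    if (df["P"] <= 0).any():
        snp = df.loc[df["P"] <= 0, "SNP"].iloc[0]
        raise DataError(
            f"{path}: non-positive p-value at SNP {snp!r}; clamp p to >= 1e-300 upstream"
        )
    df = df.set_index("SNP")
    return validate_sumstats(df)


def write_sumstats(stats: pd.DataFrame, path) -> None:
    validate_sumstats(stats)
    out = stats.reset_index()
    first = "SNP" if "SNP" in out.columns else out.columns[0]
    out = out.rename(columns={first: "SNP"})
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA"]
    cols += [c for c in ("SE",) if c in out]
    cols += ["P"] + [c for c in ("N",) if c in out]
    out[cols].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# genotypes
def write_genotypes_vcf(genos: DosageMatrix, path) -> None:
    """Write dosages as a VCF with a per-sample ``DS`` FORMAT field."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=IMPINFO,Number=1,Type=Float,'
                 'Description="Imputation quality score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genos.samples)) + "\n")
        v = genos.variants
        for j, (snp, row) in enumerate(v.iterrows()):
            ds = genos.dosages[:, j]
            vals = "\t".join("." if np.isnan(x) else f"{x:.6g}" for x in ds)
            fh.write(
                f"{row['CHR']}\t{row['BP']}\t{snp}\t{row['A2']}\t{row['A1']}\t.\t"
                f"PASS\tIMPINFO={row['INFO']:.4g}\tDS\t{vals}\n"
            )


def _read_vcf(path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples, name="IID")
    rows, meta, ids = [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise DataError(f"{path}: record {var.ID} lacks the DS format field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        ds = np.where((ds < -1e-6) | (ds > 2 + 1e-6), np.nan, ds)
        rows.append(ds)
        info = var.INFO.get("IMPINFO")
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        meta.append(
            {"CHR": int(var.CHROM) if str(var.CHROM).isdigit() else var.CHROM,
             "BP": var.POS, "A1": var.ALT[0], "A2": var.REF,
             "INFO": 1.0 if info is None else float(info)}
        )
    if not rows:
        raise DataError(f"{path}: no variant records")
    variants = pd.DataFrame(meta, index=pd.Index(ids, name="SNP"))
    if variants.index.has_duplicates:
        variants = variants.loc[~variants.index.duplicated()]
        rows = [r for r, keep in zip(rows, ~pd.Index(ids).duplicated()) if keep]
    return DosageMatrix(np.column_stack(rows), samples, variants)


def write_genotypes_tsv(genos: DosageMatrix, path) -> None:
    """Write a dosage TSV (IID + per-variant columns) with a
    ``<stem>.variants.tsv`` metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(genos.dosages, index=genos.samples,
                      columns=genos.variants.index)
    df.to_csv(path, sep="\t", index_label="IID", float_format="%.6g")
    sidecar = path.with_suffix(".variants.tsv")
    genos.variants.to_csv(sidecar, sep="\t", index_label="SNP")


def read_genotypes(path, fmt: str | None = None) -> DosageMatrix:
    """Read genotypes from VCF or dosage TSV (format inferred from the
    extension when ``fmt`` is None)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt != "dosage-tsv":
        raise DataError(f"unknown genotype format {fmt!r}")
    sidecar = path.with_suffix(".variants.tsv")
    if not sidecar.exists():
        raise DataError(f"dosage TSV requires the metadata sidecar {sidecar}")
    df = pd.read_csv(path, sep="\t", index_col="IID")
    variants = pd.read_csv(sidecar, sep="\t", index_col="SNP")
    if list(df.columns) != list(variants.index):
        raise DataError("dosage columns and variant sidecar disagree")
    df = df.loc[~df.index.duplicated()]
    return DosageMatrix(df.to_numpy(dtype=float), df.index, variants)


# --------------------------------------------------------------------------- #
# phenotypes, genes, profiles
def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise DataError(f"{path}: missing IID column")
    df = df.set_index("IID")
    for col in ("RESPONSE", "REMISSION"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if not vals.dropna().isin([0, 1]).all():
                raise DataError(f"{path}: {col} must be binary 0/1")
            df[col] = vals
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="IID")


def read_genes_bed(path) -> pd.DataFrame:
    """Read a 4-column BED of gene intervals (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    if df[["start", "end"]].isna().any().any():
        raise DataError(f"{path}: malformed BED intervals")
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "name"].tolist()
        raise DataError(f"{path}: end <= start for {bad[:5]}")
    return df


def write_profile(profile: PgsProfile, path) -> None:
    """Write scores as TSV plus a YAML sidecar with M_T and parameters."""
    path = Path(path)
    profile.scores.to_csv(path, sep="\t", index_label="IID", float_format="%.10g")
    side = {
        "trait": profile.trait,
        "m_t": {float(t): int(m) for t, m in profile.m_t.items()},
        "clump_params": asdict(profile.clump_params) if profile.clump_params else None,
        "thresholds": list(profile.grid) if profile.grid else sorted(profile.m_t),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def read_profile(path) -> PgsProfile:
    path = Path(path)
    scores = pd.read_csv(path, sep="\t", index_col="IID")
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    grid = ThresholdGrid(tuple(side["thresholds"]))
    cp = ClumpParams(**side["clump_params"]) if side.get("clump_params") else None
    return PgsProfile(scores, {float(t): int(m) for t, m in side["m_t"].items()},
                      trait=side.get("trait", ""), clump_params=cp, grid=grid)


# --------------------------------------------------------------------------- #
# pipeline
@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    With ``simulate=True`` the run generates its own cohort; otherwise the
    genotype/sumstats/phenotype paths must resolve. Constants default to
    the published analysis: QC bounds (0.95, 0.01, 1e-6, 0.10, 0.9),
    clumping r2 = 0.1 in a 250-kb window, the 8-cutoff threshold grid and
    significance levels 5e-8 / 0.05 / 5% FDR.
    """

    outdir: str = "pgx_run"
    simulate: bool = True
    n_samples: int = 1394
    ld_blocks: int = 250
    snps_per_block: int = 20
    seed: int = 0
    trait: str = "openness"
    genotypes: str | None = None
    sumstats: str | None = None
    phenotypes: str | None = None
    genes_bed: str | None = None
    crosstrait_with: str | None = None  # second sumstats path (or None)
    outcomes: tuple = ("RESPONSE", "REMISSION")
    covariates: tuple = ("AGE", "SEX")
    qc: QcThresholds = field(default_factory=QcThresholds)
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    genome_wide_p: float = 5e-8
    nominal_p: float = 0.05
    fdr_level: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("qc", QcThresholds), ("clump_params", ClumpParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "grid" in raw and isinstance(raw["grid"], (list, tuple)):
            raw["grid"] = ThresholdGrid(tuple(raw["grid"]))
        for key in ("outcomes", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for k in ("genome_wide_p", "nominal_p", "fdr_level"):
            v = getattr(cfg, k)
            if not (0 < v < 1):
                raise DataError(f"{k} must lie in (0, 1)")
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["outcomes"] = list(self.outcomes)
        d["covariates"] = list(self.covariates)
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[pgxpersona] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute qc -> harmonize -> clump -> score -> assoc (every outcome),
    plus the optional cross-trait stage; writes all outputs and a manifest."""
    from . import __version__
    from .assoc import PgsAssociation
    from .crosstrait import CrossTraitMeta
    from .simdata import simulate_cohort

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the hash covers the analysis-relevant settings, not output locations
    cfg_dict = yaml.safe_load(config.to_yaml())
    cfg_dict.pop("outdir", None)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            yaml.safe_dump(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        from .simdata import LdBlockSpec

        _log(f"simulating cohort (n={config.n_samples}, seed={config.seed})")
        sim = simulate_cohort(
            n_samples=config.n_samples,
            ld_spec=LdBlockSpec(n_blocks=config.ld_blocks,
                                snps_per_block=config.snps_per_block),
            seed=config.seed,
        )
        genos, stats, pheno = sim["genotypes"], sim["sumstats"], sim["phenotypes"]
        write_genotypes_vcf(genos, outdir / "genotypes.vcf")
        write_sumstats(stats, outdir / "sumstats.tsv")
        write_phenotypes(pheno, outdir / "phenotypes.tsv")
    else:
        if not (config.genotypes and config.sumstats and config.phenotypes):
            raise DataError("genotypes, sumstats and phenotypes paths required")
        genos = read_genotypes(config.genotypes)
        stats = read_sumstats(config.sumstats)
        pheno = read_phenotypes(config.phenotypes)
    for cov in config.covariates:
        if cov not in pheno.columns:
            raise DataError(f"unknown covariate {cov!r} in config")
    manifest.stage_counts["input"] = {
        "samples": genos.n_samples, "variants": genos.n_variants,
        "sumstats": len(stats),
    }

    # ---- qc ---------------------------------------------------------------
    genos, report = apply_qc(genos, config.qc)
    (outdir / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _log(f"qc: {report.n_samples_out} samples, {report.n_variants_out} variants retained")
    manifest.stage_counts["qc"] = {
        "samples": report.n_samples_out, "variants": report.n_variants_out,
    }

    # ---- harmonize + clump + score ---------------------------------------
    stats_h = harmonize_alleles(stats, genos)
    retained = clump(stats_h, genos, config.clump_params)
    _log(f"clump: {len(retained)} index SNPs")
    profile = compute_pgs(genos, stats_h, retained, config.grid,
                          trait=config.trait, clump_params=config.clump_params)
    write_profile(profile, outdir / "profile.tsv")
    manifest.stage_counts["pgs"] = {
        "clumped": len(retained),
        "m_t": {f"{t:g}": m for t, m in profile.m_t.items()},
    }

    # ---- association ------------------------------------------------------
    for outcome in config.outcomes:
        res = PgsAssociation(profile, pheno, outcome, list(config.covariates)).fit()
        stem = outdir / f"assoc_{outcome.lower()}"
        res.table.to_csv(f"{stem}_scan.tsv", sep="\t", index=False)
        res.quartile_table.to_csv(f"{stem}_quartiles.tsv", sep="\t")
        ax = res.plot_delta_r2()
        ax.figure.savefig(f"{stem}_delta_r2.png", dpi=100)
        ax2 = res.plot_quartile_ors()
        ax2.figure.savefig(f"{stem}_quartiles.png", dpi=100)
        import matplotlib.pyplot as plt

        plt.close("all")
        _log(
            f"assoc {outcome}: optimal P_T={res.optimal_threshold:g}, "
            f"delta-R2={res.scan.optimal_row['delta_r2'] * 100:.2f}%"
        )
        manifest.stage_counts[f"assoc_{outcome}"] = {
            "optimal_p_t": res.optimal_threshold,
            "thresholds": int(len(res.table)),
        }

    # ---- cross-trait (optional) ------------------------------------------
    if config.crosstrait_with:
        stats2 = read_sumstats(config.crosstrait_with)
        res = CrossTraitMeta(stats_h, stats2).fit(
            gw_threshold=config.genome_wide_p, nominal=config.nominal_p
        )
        res.assign_loci(genos)
        if config.genes_bed:
            res.annotate(read_genes_bed(config.genes_bed))
        table = getattr(res, "annotated", res.loci)
        table.to_csv(outdir / "crosstrait_hits.tsv", sep="\t", index_label="SNP")
        manifest.stage_counts["crosstrait"] = {
            "shared": len(res.hits), "significant": int(res.hits["pass_dual"].sum()),
        }

    for f in sorted(outdir.iterdir()):
        if f.suffix in (".tsv", ".vcf", ".json", ".yaml"):
            manifest.output_hashes[f.name] = _sha256(f)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
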