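"""Domain containers, loaders, allele harmonization and result writing.

Every table the pipeline touches passes through here: GWAS summary
statistics, cis-meQTL/eQTL weight models, the LD reference panel,
methylation/expression matrices with sample metadata, and gene-model /
LD-block annotations. Coordinates are 1-based inclusive throughout
(GWAS convention); BED block files (0-based half-open) are converted on
read and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methlink")

GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

WEIGHT_COLUMNS = [
    "unit_id", "unit_chrom", "unit_pos", "snp_id",
    "effect_allele", "other_allele", "weight",
]

#: canonical column order for association tables (the currency passed
#: between discovery, overlap and characterisation stages)
ASSOC_COLUMNS = [
    "unit_id", "z", "p", "fdr", "direction", "n_snps_used",
    "sigma_g", "analysis",
]

CIS_WINDOW = 1_000_000  # bp; cis definition used for weight models

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    """Strand-ambiguous pair: A/T or C/G (allele flip == strand flip)."""
    return _COMPLEMENT.get(a1) == a2


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GwasTable:
    """Per-SNP marginal association summary statistics.

    ``df`` holds one row per SNP with the columns in :data:`GWAS_COLUMNS`.
    ``report`` carries loader/validation accounting (rows kept/dropped).
    """

    df: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)


@dataclass
class WeightModel:
    """Cis-SNP weights predicting one CpG's (or gene's) molecular level."""

    unit_id: str
    unit_chrom: str
    unit_pos: int
    entries: pd.DataFrame  # snp_id, effect_allele, other_allele, weight

    @property
    def snp_ids(self) -> list[str]:
        return list(self.entries["snp_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(float)


@dataclass
class ReferencePanel:
    """Dosage reference used for LD (Sigma, r2) and per-SNP sd.

    ``dosages`` is samples x SNPs in [0, 2], counting the alt allele.
    Monomorphic SNPs are removed at construction.
    """

    sample_ids: list[str]
    snps: pd.DataFrame  # snp_id, chrom, pos, ref_allele, alt_allele
    dosages: np.ndarray
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix {d.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages outside [0, 2]")
        keep = d.std(axis=0) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d monomorphic SNPs from panel", n_dropped)
            self.snps = self.snps.loc[keep].reset_index(drop=True)
            d = d[:, keep]
        self.dosages = d
        self.report.setdefault("monomorphic_dropped", n_dropped)
        self._index = {s: i for i, s in enumerate(self.snps["snp_id"])}

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    @property
    def frequencies(self) -> np.ndarray:
        """Alt-allele frequencies in (0, 1)."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def sd(self) -> np.ndarray:
        """Per-SNP empirical dosage standard deviations (ddof=1)."""
        return self.dosages.std(axis=0, ddof=1)

    def columns(self, snp_ids) -> np.ndarray:
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise KeyError(f"SNPs absent from panel: {missing}")
        idx = [self._index[s] for s in snp_ids]
        return self.dosages[:, idx]

    def subset(self, snp_ids) -> "ReferencePanel":
        keep = self.snps["snp_id"].isin(set(snp_ids)).to_numpy()
        return ReferencePanel(
            sample_ids=list(self.sample_ids),
            snps=self.snps.loc[keep].copy(),
            dosages=self.dosages[:, keep],
        )


@dataclass
class OmicsMatrix:
    """Feature x sample matrix with per-sample metadata.

    ``values``: beta values in [0,1] for methylation, or non-negative
    integer counts for expression.  ``metadata`` is indexed by sample id
    and carries at least ``sample_type`` (tumour / NAT / healthy),
    ``age`` and ``group`` (batch label).
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    metadata: pd.DataFrame
    kind: str = "methylation"  # or "expression"

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.metadata = self.metadata.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values[list(sample_ids)].copy(),
            self.metadata.loc[list(sample_ids)].copy(),
            kind=self.kind,
        )


@dataclass
class AnnotationSet:
    """Gene models plus non-overlapping LD blocks.

    ``genes`` columns: gene_id, chrom, strand, tx_start, tx_end,
    cds_start, cds_end, coding, exon_starts, exon_ends (comma-joined
    1-based inclusive intervals).  ``blocks`` columns: block_id, chrom,
    start, end (1-based inclusive).
    """

    genes: pd.DataFrame
    blocks: pd.DataFrame

    def __post_init__(self):
        b = self.blocks.sort_values(["chrom", "start"])
        for _, grp in b.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if len(grp) > 1 and (starts[1:] <= ends[:-1]).any():
                raise ValueError("LD blocks overlap within a chromosome")

    def gene_exons(self, row) -> list[tuple[int, int]]:
        starts = [int(x) for x in str(row["exon_starts"]).split(",")]
        ends = [int(x) for x in str(row["exon_ends"]).split(",")]
        return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_gwas(path, column_map: dict | None = None,
              dedupe_first: bool = False) -> GwasTable:
    """Read a delimited GWAS summary-statistics file.

    Rows violating invariants (se <= 0, eaf outside (0,1), p outside
    (0,1], n <= 0, missing values) are dropped and counted in
    ``table.report``.  Duplicate snp_id is fatal unless ``dedupe_first``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS file missing mandatory columns: {missing}")
    df = df[GWAS_COLUMNS].copy()
    rows_in = len(df)

    if df["snp_id"].duplicated().any():
        if dedupe_first:
            df = df.drop_duplicates("snp_id", keep="first")
        else:
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].unique()
            raise ValueError(f"duplicate snp_id in GWAS file: {list(dups)[:5]}")

    df["chrom"] = df["chrom"].astype(str)
    ok = (
        df[GWAS_COLUMNS].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["eaf"] > 0) & (df["eaf"] < 1)
        & (df["p"] > 0) & (df["p"] <= 1)
        & (df["n"] > 0)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("load_gwas: dropped %d invalid rows", dropped)
    out = df.loc[ok].reset_index(drop=True)
    report = {"rows_in": rows_in, "rows_kept": len(out),
              "rows_dropped": rows_in - len(out)}
    return GwasTable(out, report)


def write_gwas(table: GwasTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_weight_models(path) -> list[WeightModel]:
    """Read long-format weight models; one :class:`WeightModel` per unit.

    Entries beyond the 1 Mb cis window of the unit anchor are dropped
    with a warning; units whose weights are all zero are excluded.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight file missing columns: {missing}")
    models = []
    for unit_id, grp in df.groupby("unit_id", sort=False):
        grp = grp.reset_index(drop=True)
        pos = int(grp.loc[0, "unit_pos"])
        chrom = str(grp.loc[0, "unit_chrom"])
        # cis rule: the SNP id encodes position as chrom:pos when no
        # explicit snp_pos column is present
        if "snp_pos" in grp.columns:
            snp_pos = grp["snp_pos"].astype(int)
        else:
            snp_pos = grp["snp_id"].astype(str).str.split(":").str[-1].astype(int)
        keep = (snp_pos - pos).abs() <= CIS_WINDOW
        if (~keep).any():
            logger.warning(
                "unit %s: dropped %d entries beyond the 1 Mb cis window",
                unit_id, int((~keep).sum()),
            )
        grp = grp.loc[keep]
        if grp["snp_id"].duplicated().any():
            raise ValueError(f"unit {unit_id}: duplicate entry SNPs")
        if len(grp) == 0 or (grp["weight"] == 0).all():
            logger.warning("unit %s: all-zero or empty weights, excluded", unit_id)
            continue
        entries = grp[["snp_id", "effect_allele", "other_allele", "weight"]]
        models.append(WeightModel(str(unit_id), chrom, pos,
                                  entries.reset_index(drop=True)))
    return models


def write_weight_models(models: list[WeightModel], path) -> None:
    rows = []
    for m in models:
        for _, e in m.entries.iterrows():
            rows.append((m.unit_id, m.unit_chrom, m.unit_pos, e["snp_id"],
                         e["effect_allele"], e["other_allele"], e["weight"]))
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def load_panel(path, format: str = "vcf", snp_map=None) -> ReferencePanel:
    """Load an LD reference panel from a VCF or a dosage matrix.

    ``format='vcf'``: diploid GT fields are converted to alt-allele
    dosage counts; multi-allelic records are skipped with a warning.
    ``format='dosage-matrix'``: delimited sample x SNP matrix whose
    column order matches the SNP map file (snp_id, chrom, pos,
    ref_allele, alt_allele).
    """
    if format == "vcf":
        return _load_panel_vcf(path)
    if format == "dosage-matrix":
        if snp_map is None:
            raise ValueError("dosage-matrix format requires snp_map")
        dmat = pd.read_csv(path, sep="\t", index_col=0)
        snps = pd.read_csv(snp_map, sep="\t")
        if dmat.shape[1] != len(snps):
            raise ValueError(
                f"dosage matrix has {dmat.shape[1]} SNP columns but map "
                f"lists {len(snps)} SNPs")
        snps["chrom"] = snps["chrom"].astype(str)
        return ReferencePanel(list(dmat.index.astype(str)), snps,
                              dmat.to_numpy(float))
    raise ValueError(f"unknown panel format {format!r}")


def _load_panel_vcf(path) -> ReferencePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, columns = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
        dos[gt == 2] = np.nan
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        records.append((snp_id, str(var.CHROM), int(var.POS),
                        var.REF, var.ALT[0]))
        columns.append(dos)
    if skipped:
        logger.warning("load_panel: skipped %d multi-allelic records", skipped)
    snps = pd.DataFrame(records, columns=["snp_id", "chrom", "pos",
                                          "ref_allele", "alt_allele"])
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return ReferencePanel(samples, snps, dosages,
                          report={"multiallelic_skipped": skipped})


def write_panel_dosage(panel: ReferencePanel, matrix_path, map_path) -> None:
    pd.DataFrame(panel.dosages, index=panel.sample_ids,
                 columns=panel.snp_ids).to_csv(matrix_path, sep="\t",
                                               float_format="%.17g")
    panel.snps.to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(gwas: GwasTable, models: list[WeightModel],
                      panel: ReferencePanel,
                      keep_ambiguous: bool = False):
    """Rotate GWAS and weight-model allele frames onto the panel frame.

    The panel's counted (alt) allele is the single orientation. Where a
    source's effect allele equals the panel ref allele, its beta (or
    weight) sign is flipped and eaf -> 1 - eaf.  Strand-ambiguous A/T
    and C/G SNPs are dropped unless ``keep_ambiguous``; SNPs absent from
    any one source, or with irreconcilable allele pairs, are dropped.

    Returns ``(gwas, models, panel, report)``; applying the function a
    second time is a no-op.
    """
    pan = panel.snps.set_index("snp_id")
    model_snps = set()
    for m in models:
        model_snps.update(m.snp_ids)
    shared = [s for s in panel.snp_ids
              if s in set(gwas.df["snp_id"]) and s in model_snps]

    report = {"kept": 0, "flipped_gwas": 0, "flipped_model": 0,
              "dropped_ambiguous": 0, "dropped_irreconcilable": 0,
              "dropped_missing": len(set(gwas.df["snp_id"]) | model_snps
                                     | set(panel.snp_ids)) - len(shared)}

    def orient(ea, oa, ref, alt):
        """Return +1 (aligned), -1 (flip) or None (irreconcilable)."""
        if (ea, oa) == (alt, ref):
            return 1
        if (ea, oa) == (ref, alt):
            return -1
        return None

    keep_ids, flips_gwas = [], {}
    for s in shared:
        ref, alt = pan.loc[s, "ref_allele"], pan.loc[s, "alt_allele"]
        if _is_ambiguous(ref, alt) and not keep_ambiguous:
            report["dropped_ambiguous"] += 1
            continue
        row = gwas.df.loc[gwas.df["snp_id"] == s].iloc[0]
        o = orient(row["effect_allele"], row["other_allele"], ref, alt)
        if o is None:
            report["dropped_irreconcilable"] += 1
            continue
        keep_ids.append(s)
        flips_gwas[s] = o

    gdf = gwas.df[gwas.df["snp_id"].isin(keep_ids)].copy().reset_index(drop=True)
    for i, row in gdf.iterrows():
        s = row["snp_id"]
        if flips_gwas[s] == -1:
            ref, alt = pan.loc[s, "ref_allele"], pan.loc[s, "alt_allele"]
            gdf.loc[i, ["beta", "eaf"]] = [-row["beta"], 1 - row["eaf"]]
            gdf.loc[i, ["effect_allele", "other_allele"]] = [alt, ref]
            report["flipped_gwas"] += 1
    report["kept"] = len(gdf)

    new_models = []
    for m in models:
        ent = m.entries.copy()
        keep_rows, dropped = [], 0
        for i, e in ent.iterrows():
            s = e["snp_id"]
            if s not in flips_gwas:
                dropped += 1
                continue
            if flips_gwas[s] == -1:
                ref, alt = pan.loc[s, "ref_allele"], pan.loc[s, "alt_allele"]
                ent.loc[i, "weight"] = -e["weight"]
                ent.loc[i, ["effect_allele", "other_allele"]] = [alt, ref]
                report["flipped_model"] += 1
            keep_rows.append(i)
        ent = ent.loc[keep_rows].reset_index(drop=True)
        if len(ent) and (ent["weight"] != 0).any():
            new_models.append(WeightModel(m.unit_id, m.unit_chrom,
                                          m.unit_pos, ent))

    new_panel = panel.subset(keep_ids)
    return GwasTable(gdf, dict(gwas.report)), new_models, new_panel, report


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV with deterministic column order and
    full float precision (reload is value-identical to 1e-12)."""
    cols = [c for c in ASSOC_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------

def write_blocks_bed(blocks: pd.DataFrame, path) -> None:
    """LD blocks to BED (0-based half-open on disk)."""
    out = blocks.copy()
    out["bed_start"] = out["start"] - 1
    out[["chrom", "bed_start", "end", "block_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_blocks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "bed_start", "end", "block_id"])
    bed["chrom"] = bed["chrom"].astype(str)
    bed["start"] = bed["bed_start"] + 1
    return bed[["block_id", "chrom", "start", "end"]]


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_omics(matrix: OmicsMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.17g")
    matrix.metadata.to_csv(meta_path, sep="\t")


def read_omics(values_path, meta_path, kind="methylation") -> OmicsMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return OmicsMatrix(values, meta, kind=kind)
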