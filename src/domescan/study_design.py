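"""Published sampling design of the two-species domestication study.

Gilthead seabream (*Sparus aurata*) and European seabass (*Dicentrarchus
labrax*) were each genotyped two ways: Sanger-sequenced amplicons of the
*vgll3* and *six6* candidate genes in individually sampled farmed and wild
fish ("gene level"), and whole-genome sequencing of pooled populations
("chromosome level", Pool-Seq).  This module records that design — the
per-population sample counts with collection years, the amplicon
coordinates, the pool layout, and the annotated genes flanking the
reported differentiation peaks — as plain data.  The synthetic generators
default to these layouts and the bookkeeping helpers below let analyses
reproduce the study's sample-size arithmetic.

Coordinate conventions: amplicon sizes follow the source table's
``end - start`` convention; gene spans are 1-based inclusive (GFF3).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "gene_level_design",
    "amplicons",
    "amplicon_length",
    "pool_design",
    "peak_genes",
    "peak_gene_gff3",
    "total_genotyped",
]

# ---------------------------------------------------------------------------
# Gene-level sampling: one row per population; n_vgll3 / n_six6 are the
# numbers of individuals genotyped for each gene (None = not genotyped).
# Collection periods are binary: "2004-2007" (early) vs "2012-2016" (late).
# ---------------------------------------------------------------------------

_GENE_LEVEL_ROWS = [
    # species, pop_id, origin, year, n_vgll3, n_six6
    ("seabream", "seabream_w1.1", "wild", 2004, 5, 4),
    ("seabream", "seabream_w1.2", "wild", 2004, 5, 5),
    ("seabream", "seabream_w1.3", "wild", 2005, 5, 3),
    ("seabream", "seabream_w1.4", "wild", 2005, 5, 5),
    ("seabream", "seabream_w1.5", "wild", 2005, 5, 5),
    ("seabream", "seabream_w1.6", "wild", 2006, 5, 3),
    ("seabream", "seabream_w2.1", "wild", 2013, 5, 5),
    ("seabream", "seabream_w2.2", "wild", 2013, 5, 5),
    ("seabream", "seabream_w2.3", "wild", 2013, 5, 5),
    ("seabream", "seabream_w2.4", "wild", 2014, 4, 4),
    ("seabream", "seabream_w2.5", "wild", 2016, 5, 1),
    ("seabream", "seabream_f1.1", "farmed", 2004, 4, 4),
    ("seabream", "seabream_f1.2", "farmed", 2005, 4, 4),
    ("seabream", "seabream_f1.3", "farmed", 2005, 3, 2),
    ("seabream", "seabream_f1.4", "farmed", 2007, 5, 8),
    ("seabream", "seabream_f2.1", "farmed", 2014, 5, 5),
    ("seabream", "seabream_f2.2", "farmed", 2016, 2, None),
    ("seabream", "seabream_f2.3", "farmed", 2014, 4, 3),
    ("seabream", "seabream_f2.4", "farmed", 2014, 5, 4),
    ("seabream", "seabream_f2.5", "farmed", 2014, 5, 4),
    ("seabass", "seabass_w1.1", "wild", 2004, 5, 5),
    ("seabass", "seabass_w1.2", "wild", 2004, 5, 5),
    ("seabass", "seabass_w1.3", "wild", 2004, 5, 5),
    ("seabass", "seabass_w1.4", "wild", 2005, 5, 4),
    ("seabass", "seabass_w1.5", "wild", 2005, 5, 5),
    ("seabass", "seabass_w2.1", "wild", 2013, 4, 4),
    ("seabass", "seabass_w2.2", "wild", 2013, 5, 5),
    ("seabass", "seabass_w2.3", "wild", 2013, 4, 4),
    ("seabass", "seabass_w2.4", "wild", 2014, 5, 5),
    ("seabass", "seabass_w2.5", "wild", 2016, 3, 2),
    ("seabass", "seabass_w2.6", "wild", 2016, 6, 2),
    ("seabass", "seabass_f1.1", "farmed", 2004, 9, 7),
    ("seabass", "seabass_f1.2", "farmed", 2004, 9, 11),
    ("seabass", "seabass_f2.1", "farmed", 2014, 5, 5),
    ("seabass", "seabass_f2.2", "farmed", 2014, 4, 5),
    ("seabass", "seabass_f2.3", "farmed", 2014, 4, 5),
    ("seabass", "seabass_f2.4", "farmed", 2014, 3, 4),
    ("seabass", "seabass_f2.5", "farmed", 2016, 4, 4),
]


def _period(year: int) -> str:
    return "2004-2007" if year <= 2007 else "2012-2016"


def gene_level_design(species: str | None = None) -> pd.DataFrame:
    """Per-population gene-level sampling design.

    Returns a frame with columns ``species, pop_id, origin, year, period,
    n_vgll3, n_six6`` (individuals genotyped per gene), optionally
    restricted to one species.
    """
    df = pd.DataFrame(
        _GENE_LEVEL_ROWS,
        columns=["species", "pop_id", "origin", "year", "n_vgll3", "n_six6"],
    )
    df.insert(4, "period", df["year"].map(_period))
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown species {species!r}")
    return df


def total_genotyped(species: str, gene: str) -> int:
    """Total individuals genotyped for one gene, summed over populations."""
    col = f"n_{gene}"
    df = gene_level_design(species)
    if col not in df:
        raise ValueError(f"unknown gene {gene!r}")
    return int(df[col].dropna().sum())


# ---------------------------------------------------------------------------
# Amplicons: Sanger-sequenced regions per species and gene.  Coordinates on
# the assemblies GCA_900880675.2 (seabream) / GCA_000689215.1 (seabass);
# size is the printed amplicon length (= end - start).
# ---------------------------------------------------------------------------

_AMPLICON_ROWS = [
    # species, gene, start, end, anneal_c, size_bp, polymorphic
    ("seabass", "vgll3", 9_203_305, 9_203_951, 63, 646, True),
    ("seabass", "vgll3", 9_202_574, 9_203_170, 61, 596, False),
    ("seabass", "vgll3", 9_201_705, 9_202_720, 63, 1015, False),
    ("seabass", "vgll3", 9_201_381, 9_201_802, 61, 421, False),
    ("seabass", "six6", 11_589_507, 11_590_303, 61, 796, False),
    ("seabass", "six6", 11_590_632, 11_591_488, 63, 856, True),
    ("seabass", "six6", 11_588_596, 11_589_739, 61, 1149, False),
    ("seabass", "six6", 11_592_056, 11_592_572, 61, 515, False),
    ("seabream", "vgll3", 24_911_798, 24_912_208, 63, 410, True),
    ("seabream", "vgll3", 24_910_950, 24_911_675, 63, 725, False),
    ("seabream", "vgll3", 24_910_316, 24_911_343, 63, 1027, False),
    ("seabream", "vgll3", 24_909_934, 24_910_621, 61, 687, False),
    ("seabream", "six6", 14_404_868, 14_405_650, 61, 782, False),
    ("seabream", "six6", 14_406_022, 14_406_799, 63, 777, True),
    ("seabream", "six6", 14_403_964, 14_405_087, 63, 1123, False),
    ("seabream", "six6", 14_407_370, 14_407_840, 63, 470, False),
]


def amplicons(species: str | None = None, gene: str | None = None) -> pd.DataFrame:
    """Amplicon table: species, gene, start, end, annealing temp, size."""
    df = pd.DataFrame(
        _AMPLICON_ROWS,
        columns=["species", "gene", "start", "end", "anneal_c", "size_bp", "polymorphic"],
    )
    if species is not None:
        df = df[df["species"] == species]
    if gene is not None:
        df = df[df["gene"] == gene]
    return df.reset_index(drop=True)


def amplicon_length(start: int, end: int) -> int:
    """Amplicon length under the design table's convention (end - start)."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start


# ---------------------------------------------------------------------------
# Pool-Seq layout: one row per population pool (individuals pooled per
# population; 1-2 technical sequencing replicates per pool).
# ---------------------------------------------------------------------------

_POOL_ROWS = [
    ("seabream", "Seabream_f1", "farmed", "France", 25, 2),
    ("seabream", "Seabream_f2", "farmed", "Spain", 25, 2),
    ("seabream", "Seabream_f3", "farmed", "Spain", 25, 2),
    ("seabream", "Seabream_f4", "farmed", "Italy", 25, 1),
    ("seabream", "Seabream_f5", "farmed", "Croatia", 25, 2),
    ("seabream", "Seabream_f6", "farmed", "Greece", 14, 1),
    ("seabream", "Seabream_f7", "farmed", "Greece", 13, 1),
    ("seabream", "Seabream_f8", "farmed", "Greece", 25, 2),
    ("seabream", "Seabream_f9", "farmed", "Greece", 25, 2),
    ("seabream", "Seabream_f10", "farmed", "Greece", 25, 2),
    ("seabream", "Seabream_f11", "farmed", "Israel", 25, 2),
    ("seabream", "Seabream_f12", "farmed", "Egypt", 15, 1),
    ("seabream", "Seabream_w1", "wild", "Spain", 25, 2),
    ("seabream", "Seabream_w2", "wild", "Spain", 25, 2),
    ("seabream", "Seabream_w3", "wild", "Tunisia", 25, 2),
    ("seabream", "Seabream_w4", "wild", "Italy", 25, 2),
    ("seabream", "Seabream_w5", "wild", "Italy", 25, 2),
    ("seabream", "Seabream_w6", "wild", "Greece", 25, 2),
    ("seabream", "Seabream_w7", "wild", "Greece", 25, 2),
    ("seabream", "Seabream_w8", "wild", "Greece", 25, 2),
    ("seabream", "Seabream_w9", "wild", "Greece", 25, 2),
    ("seabream", "Seabream_w10", "wild", "Greece", 25, 2),
    ("seabream", "Seabream_w11", "wild", "Turkey", 25, 2),
    ("seabream", "Seabream_w12", "wild", "Turkey", 25, 2),
    ("seabass", "Seabass_f1", "farmed", "France", 12, 1),
    ("seabass", "Seabass_f2", "farmed", "Spain", 25, 2),
    ("seabass", "Seabass_f3", "farmed", "Spain", 25, 2),
    ("seabass", "Seabass_f4", "farmed", "Italy", 25, 2),
    ("seabass", "Seabass_f5", "farmed", "Croatia", 25, 2),
    ("seabass", "Seabass_f6", "farmed", "Croatia", 25, 2),
    ("seabass", "Seabass_f7", "farmed", "Greece", 25, 2),
    ("seabass", "Seabass_f8", "farmed", "Greece", 25, 2),
    ("seabass", "Seabass_f9", "farmed", "Greece", 25, 2),
    ("seabass", "Seabass_f10", "farmed", "Greece", 25, 2),
    ("seabass", "Seabass_f11", "farmed", "Greece", 25, 2),
    ("seabass", "Seabass_f12", "farmed", "Greece", 25, 1),
    ("seabass", "Seabass_f13", "farmed", "Cyprus", 25, 2),
    ("seabass", "Seabass_f14", "farmed", "Egypt", 15, 1),
    ("seabass", "Seabass_w1", "wild", "France", 25, 2),
    ("seabass", "Seabass_w2", "wild", "Spain", 11, 1),
    ("seabass", "Seabass_w3", "wild", "Morocco", 25, 2),
    ("seabass", "Seabass_w4", "wild", "Italy", 25, 2),
    ("seabass", "Seabass_w5", "wild", "Croatia", 12, 1),
    ("seabass", "Seabass_w6", "wild", "Greece", 25, 2),
    ("seabass", "Seabass_w7", "wild", "Greece", 25, 2),
    ("seabass", "Seabass_w8", "wild", "Cyprus", 15, 1),
    ("seabass", "Seabass_w9", "wild", "Turkey", 25, 2),
    ("seabass", "Seabass_w10", "wild", "Turkey", 25, 2),
]


def pool_design(species: str | None = None) -> pd.DataFrame:
    """Pool-Seq layout: pool id, origin, country, pool size, replicates."""
    df = pd.DataFrame(
        _POOL_ROWS,
        columns=["species", "pool_id", "origin", "country", "n_individuals", "n_replicates"],
    )
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown species {species!r}")
    return df


# ---------------------------------------------------------------------------
# Annotated genes / regulatory elements within 100 kbp of the reported
# differentiation peaks (gene spans 1-based inclusive).
# ---------------------------------------------------------------------------

_PEAK_GENE_ROWS = [
    # species, chrom, peak_pos, feature, symbol, start, end
    ("seabream", "L537129.1", 22_460_410, "CpG island", "CpG", 22_430_167, 22_430_571),
    ("seabass", "HG916832.1", 16_286_816, "Retinitis pigmentosa GTPase regulator", "rpgr", 16_239_969, 16_244_529),
    ("seabass", "HG916832.1", 16_286_816, "Ornithine carbamoyltransferase", "oct", 16_245_284, 16_249_612),
    ("seabass", "HG916832.1", 16_286_816, "G-protein-coupled receptor 161", "gpr161", 16_252_778, 16_258_234),
    ("seabass", "HG916832.1", 16_286_816, "ddb1 and cul4-associated factor 6", "dcaf6", 16_261_017, 16_284_118),
    ("seabass", "HG916832.1", 16_286_816, "Mitochondrial pyruvate carrier 2", "mpc2", 16_286_421, 16_291_829),
    ("seabass", "HG916832.1", 16_286_816, "Ribosomal protein L24", "rpl24", 16_293_485, 16_297_194),
    ("seabass", "HG916832.1", 16_286_816, "Centrosomal protein 97", "cep97", 16_298_565, 16_302_322),
    ("seabass", "HG916832.1", 16_286_816, "Neurexophilin and PC-esterase domain family, member 3", "nxpe3", 16_304_395, 16_307_184),
    ("seabass", "HG916832.1", 16_286_816, "Malic enzyme 3, NADP(+)-dependent, mitochondrial", "me3", 16_313_335, 16_324_581),
    ("seabass", "HG916832.1", 16_286_816, "Immunoglobulin-like domain containing receptor 1b", "ildr1", 16_325_825, 16_335_625),
    ("seabass", "HG916829.1", 12_321_585, "Membrane-bound O-acyltransferase domain containing 2a", "mboat2", 12_277_343, 12_318_144),
    ("seabass", "HG916829.1", 12_321_585, "Kinase D-interacting substrate 220a", "kidin220", 12_326_653, 12_365_899),
    ("seabass", "HG916829.1", 12_321_585, "Inhibitor of DNA binding 2a", "id2", 12_368_259, 12_370_413),
]


def peak_genes(species: str | None = None, chrom: str | None = None) -> pd.DataFrame:
    """Genes/regulatory elements near the reported differentiation peaks."""
    df = pd.DataFrame(
        _PEAK_GENE_ROWS,
        columns=["species", "chrom", "peak_pos", "feature", "symbol", "start", "end"],
    )
    if species is not None:
        df = df[df["species"] == species]
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    return df.reset_index(drop=True)


def peak_gene_gff3(species: str, chrom: str) -> str:
    """Minimal GFF3 text for the peak-neighbourhood genes of one chromosome.

    Reconstructed from the published gene coordinates (not an export of the
    original annotation release); gene features only, with ID/Name
    attributes.
    """
    df = peak_genes(species=species, chrom=chrom)
    if df.empty:
        raise ValueError(f"no recorded peak genes for {species!r} / {chrom!r}")
    lines = ["##gff-version 3"]
    for _, r in df.iterrows():
        attrs = f"ID=gene:{r.symbol};Name={r.symbol}"
        lines.append(
            f"{r.chrom}\tstudy_design\tgene\t{r.start}\t{r.end}\t.\t+\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"
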