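"""Genome windowing, MAF classification and rare-variant collapsing.

Variants live in a :class:`VariantTable` holding dosage genotypes (expected
alternate-allele counts in ``[0, 2]``, possibly fractional).  Chromosomes are
tiled by fixed-width windows using BED-style 0-based half-open coordinates on
``position - 1``: window ``k`` is ``[k*w, (k+1)*w)`` and a 1-based variant
position ``p`` falls in window ``(p - 1) // w``.

Within a window, variants with folded MAF below the threshold (strict ``<``)
are rare.  Maximal runs of consecutive rare variants delimited by common
variants form collapsing groups; leading/trailing runs with only one common
flank each form their own group.  A group is aggregated row-wise by sum
(``sum-adjacent``) or maximum (``max-adjacent``), yielding the collapsed rare
block ``V`` next to the untouched common block ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VariantTable",
    "Window",
    "CollapsedBlocks",
    "make_windows",
    "classify_by_maf",
    "collapse",
    "prune_degenerate",
    "read_vcf",
    "read_dosage_tsv",
    "write_windows_bed",
]

STRATEGIES = ("sum-adjacent", "max-adjacent")


@dataclass
class VariantTable:
    """Dosage matrix (individuals x variants) plus per-variant coordinates."""

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != self.pos.size:
            raise ValueError("dosage matrix must be n_individuals x n_variants")
        if self.pos.size and (np.min(self.dosages) < 0 or np.max(self.dosages) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.pos.size

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency from mean dosage over all individuals."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class Window:
    """0-based half-open genome interval with indices of contained variants."""

    chrom: object
    start: int
    end: int
    variant_indices: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


@dataclass
class CollapsedBlocks:
    """Common-variant block Z and collapsed rare block V for one window.

    ``z_indices`` are the variant-table indices behind the T columns of Z;
    ``groups`` maps each of the S columns of V to the rare-variant indices it
    aggregates.
    """

    Z: np.ndarray
    V: np.ndarray
    z_indices: list[int]
    groups: list[list[int]]
    strategy: str

    @property
    def n_common(self) -> int:
        return self.Z.shape[1]

    @property
    def n_rare_groups(self) -> int:
        return self.V.shape[1]

    def matrix(self) -> np.ndarray:
        """Concatenated [Z | V] design for the genetic part of the test."""
        return np.hstack([self.Z, self.V])


def make_windows(variants: VariantTable, width: int) -> list[Window]:
    """Tile each chromosome with fixed-width windows from position 1.

    Windows run contiguously up to the last variant position (the final
    window of a chromosome may be shorter); empty windows are kept so that a
    scan can report them as untestable.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: list[Window] = []
    for c in variants.chromosomes:
        on_c = np.nonzero(variants.chrom == c)[0]
        pos = variants.pos[on_c]
        max_pos = int(pos.max())
        n_win = (max_pos + width - 1) // width
        bins = (pos - 1) // width
        for k in range(n_win):
            idx = on_c[bins == k]
            windows.append(
                Window(
                    chrom=c,
                    start=k * width,
                    end=min((k + 1) * width, max_pos),
                    variant_indices=idx,
                )
            )
    return windows


def classify_by_maf(variants: VariantTable, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask, True where the variant is rare (folded MAF strictly below
    ``threshold``)."""
    return variants.maf() < threshold


def collapse(
    window: Window,
    variants: VariantTable,
    rare_mask: np.ndarray,
    strategy: str = "sum-adjacent",
) -> CollapsedBlocks:
    """Collapse a window's rare variants into per-adjacency-run scores."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")
    if window.n_variants == 0:
        raise ValueError(
            f"window {window.chrom}:{window.start}-{window.end} holds no variants"
        )
    z_indices: list[int] = []
    groups: list[list[int]] = []
    run: list[int] = []
    for idx in window.variant_indices:
        if rare_mask[idx]:
            run.append(int(idx))
        else:
            if run:
                groups.append(run)
                run = []
            z_indices.append(int(idx))
    if run:
        groups.append(run)
    n = variants.n_individuals
    Z = variants.dosages[:, z_indices] if z_indices else np.empty((n, 0))
    if groups:
        agg = np.sum if strategy == "sum-adjacent" else np.max
        V = np.column_stack(
            [agg(variants.dosages[:, g], axis=1) for g in groups]
        )
    else:
        V = np.empty((n, 0))
    return CollapsedBlocks(Z=Z, V=V, z_indices=z_indices, groups=groups, strategy=strategy)


def prune_degenerate(blocks: CollapsedBlocks, tol: float = 0.0) -> CollapsedBlocks:
    """Drop zero-variance (monomorphic) columns from Z and V.

    Such columns make the pooled covariance singular without carrying any
    case/control contrast; they are removed before testing and the retained
    column count feeds the degrees of freedom.
    """
    keep_z = [k for k in range(blocks.Z.shape[1]) if np.std(blocks.Z[:, k]) > tol]
    keep_v = [k for k in range(blocks.V.shape[1]) if np.std(blocks.V[:, k]) > tol]
    return CollapsedBlocks(
        Z=blocks.Z[:, keep_z],
        V=blocks.V[:, keep_v],
        z_indices=[blocks.z_indices[k] for k in keep_z],
        groups=[blocks.groups[k] for k in keep_v],
        strategy=blocks.strategy,
    )


def read_vcf(path: str) -> VariantTable:
    """Load dosages from a VCF: the DS FORMAT field when present, else the
    genotype alternate-allele count."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, ids, cols = [], [], [], []
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            cols.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            gts = np.asarray(var.gt_types, dtype=float)
            # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            dose = np.where(gts == 3, 2.0, np.where(gts == 1, 1.0, 0.0))
            cols.append(dose)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        dosages=dosages,
        samples=samples,
    )


def read_dosage_tsv(path: str) -> VariantTable:
    """Plain dosage matrix: header ``chrom pos id <sample...>``, one variant
    per row."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    samples = list(df.columns[3:])
    return VariantTable(
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        pos=df.iloc[:, 1].to_numpy(dtype=np.int64),
        ids=df.iloc[:, 2].to_numpy(dtype=object),
        dosages=df.iloc[:, 3:].to_numpy(dtype=float).T,
        samples=samples,
    )


def write_windows_bed(windows: list[Window], path: str) -> None:
    with open(path, "w") as fh:
        for k, w in enumerate(windows):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\twin{k}\n")
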