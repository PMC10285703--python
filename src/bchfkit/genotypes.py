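"""Genotype containers, QC filters, recoding, down-sampling and the GRM.

Dosages are carried as a dense float32 matrix (individuals x loci) in one of
two codings:

``"alt_count"``
    raw 0/1/2 counts of the alternative allele, NaN for missing;
``"centered"``
    the -1/0/+1 coding (reference homozygote / heterozygote / alternative
    homozygote) with missing values mean-imputed to ``2p - 1``.

The locus panel is a plain :class:`pandas.DataFrame` with columns
``chrom, pos, ref, alt`` (1-based positions) and, after recoding, ``freq``
(the alternative-allele frequency used for imputation and GRM scaling).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "maf_filter",
    "bin_downsample",
    "bin_downsample_panel",
    "panel_intersect",
    "recode_genotypes",
    "compute_grm",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"locus panel is missing columns: {sorted(missing)}")
    for _, sub in panel.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("positions must be non-decreasing within a chromosome")
    return panel


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix plus locus metadata."""

    ids: np.ndarray
    panel: pd.DataFrame
    codes: np.ndarray
    coding: str = "alt_count"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.codes = np.asarray(self.codes, dtype=np.float32)
        if self.codes.shape != (len(self.ids), len(self.panel)):
            raise ValueError(
                f"dosage matrix shape {self.codes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.panel)} loci"
            )
        if self.coding not in ("alt_count", "centered"):
            raise ValueError(f"unknown coding {self.coding!r}")
        _check_panel(self.panel)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def alt_frequency(self) -> np.ndarray:
        """Observed alternative-allele frequency per locus (missing-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if self.coding == "alt_count":
                return np.nanmean(self.codes, axis=0) / 2.0
            return (np.nanmean(self.codes, axis=0) + 1.0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids,
            panel=self.panel.iloc[index].reset_index(drop=True),
            codes=self.codes[:, index],
            coding=self.coding,
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=self.ids[index],
            panel=self.panel,
            codes=self.codes[index, :],
            coding=self.coding,
        )


@dataclasses.dataclass
class GRM:
    """Genomic relationship matrix with its VanRaden scaling constant."""

    ids: np.ndarray
    matrix: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: np.ndarray) -> "GRM":
        """Subset/reorder to the given individual ids."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = np.array([lookup[i] for i in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"id {exc} absent from GRM") from exc
        return GRM(ids=np.asarray(ids), matrix=self.matrix[np.ix_(idx, idx)], scale=self.scale)


def maf_filter(matrix: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain loci with minor-allele frequency >= ``threshold`` (order kept)."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = np.flatnonzero(matrix.maf() >= threshold - 1e-12)
    if keep.size == 0:
        warnings.warn("MAF filter removed every locus", stacklevel=2)
    return matrix.subset_loci(keep)


def bin_downsample_panel(panel: pd.DataFrame, n_bins: int, seed: int) -> np.ndarray:
    """Indices of at most one randomly chosen locus per equal-width bin.

    Bins are laid per chromosome, with the bin budget apportioned in
    proportion to each chromosome's spanned length; each chromosome gets at
    least one bin. Within a chromosome the span [min_pos, max_pos + 1) is cut
    into equal half-open intervals and one locus is drawn uniformly from each
    non-empty interval.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _check_panel(panel)
    panel = panel.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    chroms = list(panel["chrom"].unique())
    spans = {}
    for c in chroms:
        pos = panel.loc[panel["chrom"] == c, "pos"]
        spans[c] = int(pos.max()) - int(pos.min()) + 1
    total = sum(spans.values())
    alloc = {c: max(1, int(round(n_bins * spans[c] / total))) for c in chroms}
    chosen: list[int] = []
    for c in chroms:
        sub = np.flatnonzero((panel["chrom"] == c).to_numpy())
        pos = panel.loc[sub, "pos"].to_numpy()
        start = pos.min()
        width = spans[c] / alloc[c]
        bin_of = ((pos - start) / width).astype(np.int64)
        bin_of = np.minimum(bin_of, alloc[c] - 1)
        for b in np.unique(bin_of):
            members = sub[bin_of == b]
            chosen.append(int(rng.choice(members)))
    return np.array(sorted(chosen), dtype=np.int64)


def bin_downsample(matrix: GenotypeMatrix, n_bins: int, seed: int) -> GenotypeMatrix:
    idx = bin_downsample_panel(matrix.panel, n_bins, seed)
    return matrix.subset_loci(idx)


def _is_ambiguous(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def panel_intersect(panel: pd.DataFrame, array_panel: pd.DataFrame) -> np.ndarray:
    """Indices of panel loci present on an array panel (chrom+position match,
    alleles equal directly or up to a strand flip; ambiguous A/T and C/G
    sites are dropped; duplicate positions keep the first occurrence)."""
    _check_panel(panel)
    _check_panel(array_panel)

    def dedupe(df: pd.DataFrame, label: str) -> pd.DataFrame:
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            warnings.warn(f"{int(dup.sum())} duplicate positions in {label}; keeping first", stacklevel=2)
        return df[~dup]

    left = dedupe(panel.reset_index(drop=True).reset_index(names="orig_row"), "panel")
    right = dedupe(array_panel.reset_index(drop=True), "array panel")
    merged = left.merge(right, on=["chrom", "pos"], suffixes=("", "_arr"))
    keep = []
    for row in merged.itertuples(index=False):
        a = {row.ref, row.alt}
        b = {row.ref_arr, row.alt_arr}
        if _is_ambiguous(row.ref, row.alt) or _is_ambiguous(row.ref_arr, row.alt_arr):
            continue
        flipped = {_COMPLEMENT[row.ref], _COMPLEMENT[row.alt]}
        if a == b or flipped == b:
            keep.append(row.orig_row)
    return np.array(sorted(keep), dtype=np.int64)


def recode_genotypes(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Convert 0/1/2 alternative-allele counts to the -1/0/+1 coding.

    Missing dosages are mean-imputed to ``2p - 1`` with p the observed
    alternative-allele frequency; that frequency is stored in the panel's
    ``freq`` column for downstream GRM scaling.
    """
    if matrix.coding != "alt_count":
        raise ValueError("matrix already recoded: input must be raw 0/1/2 alt counts")
    codes = matrix.codes
    observed = codes[~np.isnan(codes)]
    if not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise ValueError("raw dosages must be 0, 1, 2 or missing")
    p = matrix.alt_frequency()
    centered = codes - 1.0
    fill = np.broadcast_to(2.0 * p - 1.0, codes.shape)
    centered = np.where(np.isnan(centered), fill, centered)
    panel = matrix.panel.copy()
    panel["freq"] = p
    return GenotypeMatrix(ids=matrix.ids, panel=panel, codes=centered, coding="centered")


def compute_grm(matrix: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM: G = W W' / c with W the frequency-centered
    dosages and c = 2 * sum_k p_k (1 - p_k), p taken from the sample."""
    if matrix.coding != "centered":
        raise ValueError("GRM requires the recoded (-1/0/+1) matrix; call recode_genotypes first")
    if "freq" in matrix.panel.columns:
        p = matrix.panel["freq"].to_numpy(dtype=np.float64)
    else:
        p = matrix.alt_frequency().astype(np.float64)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic loci present; filter before GRM construction")
    W = matrix.codes.astype(np.float64) - (2.0 * p - 1.0)
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("zero GRM scaling constant")
    G = (W @ W.T) / c
    G = 0.5 * (G + G.T)
    return GRM(ids=matrix.ids, matrix=G, scale=c)
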