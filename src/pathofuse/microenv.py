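"""Tumor-microenvironment quantification from nucleus instance/type maps.

Consumes the output of any nucleus segmenter (an integer-labeled instance
map plus an 8-bit type map with the six PanNuke-style classes: neoplastic,
inflammatory, connective, dead, non-neoplastic stromal, unlabeled) and
computes per-nucleus morphology/texture descriptors, per-type densities,
spatial cell-cell contacts (8-adjacent masks) and their per-patch
abundances, and the group-comparison statistics (rank tests and univariate
logistic odds ratios) used to contrast carrier and non-carrier patches.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skimage.feature import graycomatrix
from skimage.measure import regionprops
from skimage.segmentation import find_boundaries

from .simulate import NUCLEUS_TYPES

logger = logging.getLogger(__name__)

__all__ = ["NucleusRecord", "InteractionProfile", "ingest_nuclei",
           "nucleus_features", "FEATURE_NAMES", "cell_density",
           "detect_interactions", "interaction_abundance", "compare_groups",
           "interaction_categories"]

FEATURE_NAMES = (
    # geometric
    "area", "perimeter", "eccentricity", "solidity", "extent",
    "major_axis_length", "minor_axis_length", "circularity",
    # gray-level co-occurrence texture
    "asm", "contrast", "homogeneity", "correlation", "dissimilarity",
    "entropy",
)

MIN_PIXELS = 5


@dataclass
class NucleusRecord:
    """One segmented nucleus with its 14 morphology/texture descriptors."""

    instance_id: int
    type_id: int                       # 1..6, indexes NUCLEUS_TYPES
    centroid: tuple[float, float]
    contour: np.ndarray                # (n, 2) boundary pixel coordinates
    features: np.ndarray | None = None # 14-vector, None until computed

    @property
    def type_name(self) -> str:
        return NUCLEUS_TYPES[self.type_id - 1]


def interaction_categories() -> list[tuple[int, int]]:
    """The 15 unordered pairs of distinct nucleus types."""
    return list(itertools.combinations(range(1, len(NUCLEUS_TYPES) + 1), 2))


@dataclass
class InteractionProfile:
    """Contact counts and abundances for the 15 distinct-type pairs.

    abundance = contacts of that pair / total cells in the patch.
    Same-type contacts are excluded from the categories and tracked under
    ``same_type_contacts``.
    """

    counts: dict[tuple[int, int], int]
    total_cells: int
    same_type_contacts: int = 0

    @property
    def abundances(self) -> dict[tuple[int, int], float]:
        denom = max(self.total_cells, 1)
        return {pair: c / denom for pair, c in self.counts.items()}

    def abundance(self, type_a: int, type_b: int) -> float:
        pair = (min(type_a, type_b), max(type_a, type_b))
        return self.abundances[pair]


# ---------------------------------------------------------------------------
# ingestion and per-nucleus features
# ---------------------------------------------------------------------------

def ingest_nuclei(instance_map: np.ndarray, type_map: np.ndarray,
                  intensity: np.ndarray | None = None) -> list[NucleusRecord]:
    """Build one record per instance (0 = background).

    The type is the majority vote over the instance's pixels in `type_map`;
    the contour is the instance's 8-connected inner boundary.  Instances
    smaller than 5 pixels are dropped with a log message.  When `intensity`
    is supplied the 14 descriptors are computed immediately.
    """
    instance_map = np.asarray(instance_map)
    type_map = np.asarray(type_map)
    if instance_map.shape != type_map.shape:
        raise ValueError("instance and type maps must share a shape")
    records: list[NucleusRecord] = []
    for prop in regionprops(instance_map):
        if prop.area < MIN_PIXELS:
            logger.info("dropping instance %d with %d < %d pixels",
                        prop.label, prop.area, MIN_PIXELS)
            continue
        mask = instance_map == prop.label
        types, counts = np.unique(type_map[mask], return_counts=True)
        type_id = int(types[np.argmax(counts)])
        boundary = find_boundaries(mask, mode="inner", connectivity=2)
        contour = np.argwhere(boundary)
        rec = NucleusRecord(int(prop.label), type_id,
                            tuple(prop.centroid), contour)
        if intensity is not None:
            rec.features = nucleus_features(mask, intensity)
        records.append(rec)
    return records


def nucleus_features(mask: np.ndarray, intensity: np.ndarray | None = None,
                     glcm_levels: int = 8) -> np.ndarray:
    """14 descriptors of one nucleus: 8 geometric + 6 co-occurrence texture.

    Geometry comes from the binary mask (region-property conventions);
    circularity is 4*pi*area / perimeter^2.  Texture comes from a
    gray-level co-occurrence matrix quantised to `glcm_levels` levels over
    the instance's own intensity range, distance 1, four symmetric
    directions averaged.  Without an intensity image the six texture
    entries are NaN-flagged.
    """
    props = regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty nucleus mask")
    p = props[0]
    perimeter = max(p.perimeter, 1e-12)
    circularity = 4.0 * np.pi * p.area / perimeter**2
    geometric = [float(p.area), float(p.perimeter), float(p.eccentricity),
                 float(p.solidity), float(p.extent),
                 float(p.axis_major_length), float(p.axis_minor_length),
                 float(circularity)]
    if intensity is None:
        return np.array(geometric + [np.nan] * 6)
    sub = np.asarray(intensity, dtype=np.float64)[p.slice]
    submask = mask[p.slice]
    vals = sub[submask]
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        quant = np.ones(sub.shape, dtype=np.uint8)
    else:
        quant = np.clip(((sub - lo) / (hi - lo) * glcm_levels).astype(int),
                        0, glcm_levels - 1).astype(np.uint8) + 1
    quant[~submask] = 0       # level 0 = outside the nucleus, excluded below
    glcm = graycomatrix(quant, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=glcm_levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(np.float64)   # drop background level
    glcm = glcm.sum(axis=3)[..., 0]                # average the 4 directions
    total = glcm.sum()
    if total == 0:
        return np.array(geometric + [np.nan] * 6)
    pmat = glcm / total
    i, j = np.indices(pmat.shape)
    asm = float((pmat**2).sum())
    contrast = float((pmat * (i - j) ** 2).sum())
    homogeneity = float((pmat / (1.0 + (i - j) ** 2)).sum())
    dissimilarity = float((pmat * np.abs(i - j)).sum())
    pi_marg = pmat.sum(axis=1)
    mu_i = (np.arange(pmat.shape[0]) * pi_marg).sum()
    sd_i = np.sqrt(((np.arange(pmat.shape[0]) - mu_i) ** 2 * pi_marg).sum())
    if sd_i < 1e-12:
        correlation = 1.0      # constant texture: perfectly correlated
    else:
        correlation = float(((i - mu_i) * (j - mu_i) * pmat).sum() / sd_i**2)
    nz = pmat[pmat > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.array(geometric + [asm, contrast, homogeneity, correlation,
                                 dissimilarity, entropy])


def cell_density(records: list[NucleusRecord], area: float) -> np.ndarray:
    """Per-type cell counts divided by the region area (6-vector)."""
    if area <= 0:
        raise ValueError("region area must be positive")
    counts = np.zeros(len(NUCLEUS_TYPES))
    for rec in records:
        counts[rec.type_id - 1] += 1
    return counts / area


# ---------------------------------------------------------------------------
# spatial interactions
# ---------------------------------------------------------------------------

def detect_interactions(instance_map: np.ndarray,
                        type_map: np.ndarray | None = None,
                        ) -> list[tuple[int, int]]:
    """Unordered instance pairs whose masks are in direct contact.

    Direct contact means 8-adjacency of the segmentation masks (equivalent
    to overlap after 1-pixel dilation).  Each pair is listed once.
    """
    inst = np.asarray(instance_map)
    pairs: set[tuple[int, int]] = set()
    h, w = inst.shape
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]   # symmetric closure of 8-nbhd
    for dr, dc in shifts:
        a = inst[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        b = inst[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)]
        touching = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touching].ravel(), b[touching].ravel()):
            pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    return sorted(pairs)


def interaction_abundance(pairs: list[tuple[int, int]],
                          records: list[NucleusRecord]) -> InteractionProfile:
    """Per distinct-type-pair contact abundance within a patch.

    abundance(pair) = number of contacts between the two types / total
    cells.  Same-type contacts are excluded from the 15 categories and
    reported separately.
    """
    type_of = {rec.instance_id: rec.type_id for rec in records}
    counts = {pair: 0 for pair in interaction_categories()}
    same = 0
    for a, b in pairs:
        if a not in type_of or b not in type_of:
            raise ValueError(f"contact pair ({a}, {b}) references an unknown "
                             "instance id")
        ta, tb = type_of[a], type_of[b]
        if ta == tb:
            same += 1
            continue
        counts[(min(ta, tb), max(ta, tb))] += 1
    return InteractionProfile(counts=counts, total_cells=len(records),
                              same_type_contacts=same)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compare_groups(features: pd.DataFrame, groups) -> pd.DataFrame:
    """Rank tests and univariate logistic odds ratios per feature column.

    Two groups use the Mann-Whitney rank-sum test; more use Kruskal-Wallis.
    The odds ratio (two-group case only) comes from a univariate logistic
    fit on the standardised feature, with a Wald 95% CI.  Constant features
    get p = 1 and an undefined odds ratio.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("compare_groups needs at least two groups")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 observations")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=np.float64)
        ok = np.isfinite(x)
        xv, gv = x[ok], groups[ok]
        samples = [xv[gv == lv] for lv in levels]
        row: dict = {"feature": col}
        if np.ptp(xv) == 0:
            row.update(p_value=1.0, odds_ratio=np.nan, or_low=np.nan,
                       or_high=np.nan, or_defined=False)
        else:
            if len(levels) == 2:
                stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                             alternative="two-sided")
            else:
                stat, p = stats.kruskal(*samples)
            row["p_value"] = float(p)
            if len(levels) == 2:
                z = (xv - xv.mean()) / xv.std()
                ybin = (gv == levels[1]).astype(float)
                try:
                    fit = sm.Logit(ybin, sm.add_constant(z)).fit(disp=0)
                    beta, se = fit.params[1], fit.bse[1]
                    row.update(odds_ratio=float(np.exp(beta)),
                               or_low=float(np.exp(beta - 1.96 * se)),
                               or_high=float(np.exp(beta + 1.96 * se)),
                               or_defined=bool(np.isfinite(se)))
                except Exception:   # separation / non-convergence
                    row.update(odds_ratio=np.nan, or_low=np.nan,
                               or_high=np.nan, or_defined=False)
            else:
                row.update(odds_ratio=np.nan, or_low=np.nan, or_high=np.nan,
                           or_defined=False)
        for lv, s in zip(levels, samples):
            row[f"median_{lv}"] = float(np.median(s)) if len(s) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
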