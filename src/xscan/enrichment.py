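"""CpG annotation (CGI/shore, interval tracks, XCI-escape class via
nearest TSS) and Fisher's exact enrichment against the X-chromosome-wide
CpG background.

Fold enrichment is the ratio of proportions (k/n) / (K/N) rather than the
odds ratio, so depletion can be reported as its reciprocal on the same
scale.  The shore band is closed at 2 kb; ties in the nearest-TSS lookup
break toward the smaller TSS position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datatypes import AnnotationSet

SHORE_WIDTH = 2_000
ESCAPE_TSS_MAX_DISTANCE = 10_000


def _merged_intervals(track: pd.DataFrame, chrom: str) -> np.ndarray:
    sub = track[track["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return np.empty((0, 2), dtype=int)
    iv = sub[["start", "end"]].values.astype(int)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=int)


def _distance_to_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Distance (bp) from each position to the nearest interval; 0 inside."""
    if iv.shape[0] == 0:
        return np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    starts, ends = iv[:, 0], iv[:, 1]
    j = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    has_left = j >= 0
    inside = has_left & (pos <= ends[np.clip(j, 0, None)])
    dist[inside] = 0
    left_gap = np.where(has_left & ~inside, pos - ends[np.clip(j, 0, None)], dist)
    has_right = j + 1 < len(starts)
    right_gap = np.where(has_right, starts[np.clip(j + 1, None, len(starts) - 1)] - pos, dist)
    out = np.minimum(np.where(inside, 0, left_gap), np.where(inside, 0, right_gap))
    return np.where(inside, 0, out)


def annotate_cgi(
    positions: pd.DataFrame, cgi_track: pd.DataFrame, shore_width: int = SHORE_WIDTH
) -> np.ndarray:
    """CGI class per CpG: 'island' inside any CGI interval, 'shore' within
    the closed `shore_width` bp flanking band, else 'non-CGI'.

    `positions` needs columns chrom and pos (1-based).
    """
    out = np.full(len(positions), "non-CGI", dtype=object)
    for chrom in pd.unique(positions["chrom"].astype(str)):
        sel = positions["chrom"].astype(str).values == chrom
        iv = _merged_intervals(cgi_track, chrom)
        d = _distance_to_intervals(positions["pos"].values.astype(np.int64)[sel], iv)
        cls = np.where(d == 0, "island", np.where(d <= shore_width, "shore", "non-CGI"))
        out[sel] = cls
    return out


def annotate_tracks(
    positions: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    mark_of_track=None,
) -> pd.DataFrame:
    """Per-CpG overlap flags per mark: a CpG overlaps a mark if it lies in
    ANY interval of ANY dataset carrying that mark.

    By default the mark name is the track name up to the first '_', so
    'H3K4me3_gm12878' and 'H3K4me3_k562' are datasets of mark 'H3K4me3'.
    """
    if mark_of_track is None:
        mark_of_track = lambda name: name.split("_")[0]
    marks: dict[str, np.ndarray] = {}
    pos = positions["pos"].values.astype(np.int64)
    chroms = positions["chrom"].astype(str).values
    for name, track in tracks.items():
        mark = mark_of_track(name)
        flags = np.zeros(len(positions), dtype=bool)
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            iv = _merged_intervals(track, chrom)
            flags[sel] = _distance_to_intervals(pos[sel], iv) == 0
        marks[mark] = marks.get(mark, np.zeros(len(positions), dtype=bool)) | flags
    return pd.DataFrame(marks, index=positions.index)


def annotate_escape(
    positions: pd.DataFrame,
    tss_table: pd.DataFrame,
    max_distance: int = ESCAPE_TSS_MAX_DISTANCE,
    class_column: str = "class",
) -> tuple[np.ndarray, np.ndarray]:
    """XCI-escape class of the nearest TSS per CpG, or 'unannotated' when no
    TSS lies within `max_distance` bp.  Equidistant TSSs resolve to the one
    at the smaller position.

    Returns (classes, nearest_tss_distance).
    """
    n = len(positions)
    classes = np.full(n, "unannotated", dtype=object)
    distances = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    if tss_table.empty:
        return classes, distances
    for chrom in pd.unique(positions["chrom"].astype(str)):
        sel = np.flatnonzero(positions["chrom"].astype(str).values == chrom)
        sub = tss_table[tss_table["chrom"].astype(str) == chrom]
        if sub.empty or sel.size == 0:
            continue
        sub = sub.sort_values("pos", kind="stable").reset_index(drop=True)
        tss_pos = sub["pos"].values.astype(np.int64)
        p = positions["pos"].values.astype(np.int64)[sel]
        j = np.searchsorted(tss_pos, p)
        left = np.clip(j - 1, 0, len(tss_pos) - 1)
        right = np.clip(j, 0, len(tss_pos) - 1)
        d_left = np.abs(p - tss_pos[left])
        d_right = np.abs(tss_pos[right] - p)
        # tie -> smaller TSS position, i.e. the left candidate
        use_left = d_left <= d_right
        nearest = np.where(use_left, left, right)
        dist = np.where(use_left, d_left, d_right)
        cls = sub[class_column].values[nearest]
        within = dist <= max_distance
        classes[sel[within]] = cls[within]
        distances[sel] = dist
    return classes, distances


@dataclass
class EnrichmentResult:
    """Fisher's exact enrichment of an annotation in a target CpG set
    against the X-wide background (which contains the target)."""

    annotation_label: str
    k_in: int          # target CpGs with the annotation
    n_target: int
    K_in: int          # background CpGs with the annotation (incl. target)
    N_background: int
    odds_ratio: float
    fold: float        # (k/n) / (K/N); proportion ratio
    p: float
    direction: str     # enriched | depleted

    @property
    def fold_reported(self) -> float:
        """Fold on the reciprocal scale: >1 both for enrichment and, as
        1/fold, for depletion."""
        if not np.isfinite(self.fold) or self.fold == 0:
            return float("inf") if self.direction == "enriched" else float("nan")
        return self.fold if self.direction == "enriched" else 1.0 / self.fold

    def as_row(self) -> dict:
        return {
            "annotation": self.annotation_label,
            "k_in": self.k_in, "n_target": self.n_target,
            "K_in": self.K_in, "N_background": self.N_background,
            "odds_ratio": self.odds_ratio, "fold": self.fold,
            "fold_reported": self.fold_reported,
            "p": self.p, "direction": self.direction,
        }


def fisher_enrichment(
    target_ids,
    background_ids,
    annotated_ids,
    label: str = "annotation",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 table
    [[target&ann, target&!ann], [rest&ann, rest&!ann]] where rest =
    background minus target; the background must contain the target."""
    target = set(target_ids)
    background = set(background_ids)
    annotated = set(annotated_ids)
    if not target:
        raise ValueError("empty target CpG set")
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    rest = background - target
    k_in = len(target & annotated)
    K_in = len(background & annotated)
    a, b = k_in, len(target) - k_in
    c, d = len(rest & annotated), len(rest) - len(rest & annotated)
    odds_ratio, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    prop_t = k_in / len(target)
    prop_b = K_in / len(background)
    fold = prop_t / prop_b if prop_b > 0 else float("inf")
    direction = "enriched" if fold >= 1 else "depleted"
    return EnrichmentResult(
        label, k_in, len(target), K_in, len(background),
        float(odds_ratio), float(fold), float(p), direction,
    )


def enrichment_table(
    target_ids,
    cpg_features: pd.DataFrame,
    annotations: AnnotationSet,
    class_column: str = "class",
) -> pd.DataFrame:
    """One EnrichmentResult row per annotation label (CGI classes, interval
    marks, escape classes) for a target CpG set against all supplied CpGs."""
    positions = pd.DataFrame(
        {"id": cpg_features["id"], "chrom": cpg_features["chrom"],
         "pos": cpg_features["start"]}
    ).reset_index(drop=True)
    ids = positions["id"].values
    results = []
    if "CGI" in annotations.interval_tracks:
        cgi = annotate_cgi(positions, annotations.interval_tracks["CGI"])
        for cls in ("island", "shore", "non-CGI"):
            results.append(
                fisher_enrichment(target_ids, ids, ids[cgi == cls], f"cgi:{cls}")
            )
    other_tracks = {k: v for k, v in annotations.interval_tracks.items() if k != "CGI"}
    if other_tracks:
        flags = annotate_tracks(positions, other_tracks)
        for mark in flags.columns:
            results.append(
                fisher_enrichment(target_ids, ids, ids[flags[mark].values], f"mark:{mark}")
            )
    if len(annotations.tss_table):
        esc, _d = annotate_escape(positions, annotations.tss_table,
                                  class_column=class_column)
        for cls in ("escape", "variable", "subject"):
            present = ids[esc == cls]
            if len(present):
                results.append(
                    fisher_enrichment(target_ids, ids, present, f"escape:{cls}")
                )
    return pd.DataFrame([r.as_row() for r in results])
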