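"""Selective-sweep scan on the windowed diversity ratio pi_race/pi_cultivar.

Windows with diversity below 0.001 in BOTH groups are masked out of the
ratio track.  Windows above the threshold (default 25, strict >) merge into
sweep regions when directly adjacent; a masked or sub-threshold window
breaks a region.  The false-positive rate is estimated by permuting group
labels and recording the per-window exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeLayout, GenotypeMatrix, IntervalSet, make_windows
from .popgen_stats import window_pi

__all__ = ["sweep_ratio_profile", "call_sweeps", "permutation_fpr",
           "homoeolog_pairs", "qtl_overlap", "SweepRegion"]

LOW_DIVERSITY = 0.001


def sweep_ratio_profile(stats_race: pd.DataFrame,
                        stats_cultivar: pd.DataFrame,
                        low: float = LOW_DIVERSITY) -> pd.DataFrame:
    """Per-window diversity ratio track from two window_pi outputs.

    Both inputs must share the same window tiling.  Windows where pi is
    below ``low`` in BOTH groups (or undefined in either) are masked.
    A window with pi_cultivar = 0 but qualifying pi_race gets a +inf ratio,
    which sorts above any finite ratio.
    """
    for col in ("chrom", "start", "end"):
        if not (stats_race[col] == stats_cultivar[col]).all():
            raise ValueError("window tilings differ between the two tracks")
    pi_r = stats_race["pi"].to_numpy(float)
    pi_c = stats_cultivar["pi"].to_numpy(float)
    masked = ((pi_r < low) & (pi_c < low)) | np.isnan(pi_r) | np.isnan(pi_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi_c > 0, pi_r / np.where(pi_c > 0, pi_c, 1),
                         np.inf)
    ratio = np.where(masked, np.nan, ratio)
    out = stats_race[["chrom", "start", "end", "label"]].copy()
    out["pi_race"] = pi_r
    out["pi_cultivar"] = pi_c
    out["ratio"] = ratio
    out["masked"] = masked
    return out


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list[int]          # row indices into the ratio track
    max_ratio: float
    mean_ratio: float
    genes: list[str] = field(default_factory=list)
    qtls: list[str] = field(default_factory=list)
    partner: int | None = None  # index of homoeologous partner region


def call_sweeps(ratio_track: pd.DataFrame,
                threshold: float = 25.0) -> list[SweepRegion]:
    """Merge maximal runs of directly adjacent above-threshold windows.

    Adjacency means consecutive rows on the same chromosome whose intervals
    abut; masked windows never join or bridge a region.
    """
    regions: list[SweepRegion] = []
    run: list[int] = []

    def flush():
        if run:
            rows = ratio_track.iloc[run]
            ratios = rows["ratio"].to_numpy(float)
            finite = ratios[np.isfinite(ratios)]
            mean = float(finite.mean()) if len(finite) else np.inf
            regions.append(SweepRegion(
                chrom=rows.iloc[0]["chrom"],
                start=int(rows.iloc[0]["start"]),
                end=int(rows.iloc[-1]["end"]),
                windows=list(run),
                max_ratio=float(np.max(ratios)),
                mean_ratio=mean))
        run.clear()

    prev = None
    for i, row in enumerate(ratio_track.itertuples(index=False)):
        above = (not row.masked) and row.ratio > threshold
        contiguous = (prev is not None and row.chrom == prev.chrom
                      and row.start == prev.end)
        if above:
            if run and not contiguous:
                flush()
            run.append(i)
        else:
            flush()
        prev = row
    flush()
    return regions


def permutation_fpr(matrix: GenotypeMatrix, race_ids, cultivar_ids,
                    windows: IntervalSet, threshold: float = 25.0,
                    n_perm: int = 200, seed: int = 0,
                    low: float = LOW_DIVERSITY):
    """Label-permutation false-positive rate of the diversity-ratio scan.

    For each permutation, race/cultivar labels are reshuffled among the
    combined accessions (group sizes preserved), the ratio track is
    recomputed and the fraction of unmasked windows exceeding ``threshold``
    recorded.  Returns (mean fraction, per-permutation fractions).
    """
    if len(race_ids) < 3 or len(cultivar_ids) < 3:
        raise ValueError("need >= 3 accessions per group to permute")
    rng = np.random.default_rng(seed)
    combined = np.array(list(race_ids) + list(cultivar_ids))
    n_race = len(race_ids)
    fracs = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(combined))
        r_ids = combined[perm[:n_race]]
        c_ids = combined[perm[n_race:]]
        track = sweep_ratio_profile(
            window_pi(matrix, list(r_ids), windows),
            window_pi(matrix, list(c_ids), windows), low=low)
        unmasked = ~track["masked"]
        n_un = int(unmasked.sum())
        exceed = int(((track["ratio"] > threshold) & unmasked).sum())
        fracs[k] = exceed / n_un if n_un else 0.0
    return float(fracs.mean()), fracs


def _map_interval(chrom, start, end, link, forward: bool):
    """Linear coordinate transfer through one homoeolog link."""
    if forward:
        s0, e0 = link.a_start, link.a_end
        s1, e1 = link.d_start, link.d_end
        tgt = link.d_chrom
    else:
        s0, e0 = link.d_start, link.d_end
        s1, e1 = link.a_start, link.a_end
        tgt = link.a_chrom
    scale = (e1 - s1) / (e0 - s0)
    ms = s1 + (max(start, s0) - s0) * scale
    me = s1 + (min(end, e0) - s0) * scale
    if me <= ms:
        return None
    return tgt, int(ms), int(np.ceil(me))


def homoeolog_pairs(sweeps: list[SweepRegion], layout: GenomeLayout,
                    ratio_track: pd.DataFrame,
                    partner_threshold: float = 15.0) -> list[tuple[int, int]]:
    """Pair sweeps with homoeologous-region selection signals.

    A sweep pairs with the partner subgenome when its interval, transferred
    through the homoeolog map, covers at least one unmasked window with
    ratio > ``partner_threshold``.  Returned pairs (i, j) are indices into
    ``sweeps`` with i < j when both intervals hold called sweeps, and the
    relation is checked symmetrically.  Sweeps on chromosomes absent from
    the map raise ValueError.
    """
    mapped_chroms = {l.a_chrom for l in layout.homoeolog_map} | \
                    {l.d_chrom for l in layout.homoeolog_map}
    track_chrom = ratio_track["chrom"].to_numpy()
    track_start = ratio_track["start"].to_numpy()
    track_end = ratio_track["end"].to_numpy()
    track_ratio = ratio_track["ratio"].to_numpy(float)
    track_masked = ratio_track["masked"].to_numpy(bool)

    def signal_in(chrom, start, end) -> bool:
        sel = ((track_chrom == chrom) & (track_start < end)
               & (track_end > start) & ~track_masked)
        return bool(np.any(track_ratio[sel] > partner_threshold))

    def partner_intervals(sw: SweepRegion):
        out = []
        for link in layout.homoeolog_map:
            if sw.chrom == link.a_chrom:
                m = _map_interval(sw.chrom, sw.start, sw.end, link, True)
            elif sw.chrom == link.d_chrom:
                m = _map_interval(sw.chrom, sw.start, sw.end, link, False)
            else:
                continue
            if m:
                out.append(m)
        return out

    pairs = []
    for i, sw in enumerate(sweeps):
        if sw.chrom not in mapped_chroms:
            raise ValueError(f"sweep chromosome {sw.chrom} absent from "
                             f"homoeolog map")
        for tgt, ms, me in partner_intervals(sw):
            if not signal_in(tgt, ms, me):
                continue
            # prefer pairing with a called sweep overlapping the image
            mate = None
            for j, other in enumerate(sweeps):
                if j != i and other.chrom == tgt \
                        and other.start < me and other.end > ms:
                    mate = j
                    break
            pairs.append((i, mate))
    # deduplicate symmetric sweep-sweep pairs
    seen, out = set(), []
    for i, j in pairs:
        key = (min(i, j), max(i, j)) if j is not None else (i, None)
        if key not in seen:
            seen.add(key)
            out.append((i, j))
    return out


def qtl_overlap(sweeps: list[SweepRegion], qtls: IntervalSet) -> dict:
    """Strict half-open interval intersection between sweeps and QTLs.

    Annotates each sweep's ``qtls`` list in place and returns summary counts:
    sweeps_with_qtl, qtls_near_sweeps, and the per-sweep table.
    """
    qdf = qtls.df
    hit_qtls = set()
    rows = []
    for k, sw in enumerate(sweeps):
        sel = ((qdf["chrom"] == sw.chrom) & (qdf["start"] < sw.end)
               & (qdf["end"] > sw.start))
        labels = qdf.loc[sel, "label"].tolist()
        sw.qtls = labels
        hit_qtls.update(labels)
        rows.append((k, sw.chrom, sw.start, sw.end, len(labels),
                     ";".join(labels)))
    table = pd.DataFrame(rows, columns=["sweep", "chrom", "start", "end",
                                        "n_qtls", "qtls"])
    return {"sweeps_with_qtl": int((table["n_qtls"] > 0).sum()),
            "qtls_near_sweeps": len(hit_qtls),
            "table": table}


def scan_sweeps(matrix: GenotypeMatrix, race_ids, cultivar_ids,
                layout: GenomeLayout, window_size: int = 100_000,
                threshold: float = 25.0):
    """Convenience: windows -> pi tracks -> ratio -> sweep regions."""
    windows = make_windows(layout, window_size)
    track = sweep_ratio_profile(window_pi(matrix, race_ids, windows),
                                window_pi(matrix, cultivar_ids, windows))
    return track, call_sweeps(track, threshold)
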