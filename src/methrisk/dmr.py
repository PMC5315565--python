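"""Spatially-correlated p-value region calling (comb-p style).

Pipeline: (1) estimate the autocorrelation of probit-transformed p-values
as a function of genomic distance, in 50-bp bins out to the window size;
(2) smooth each probe's p-value with the Stouffer-Liptak-Kechris
combination of its neighbours within half a window either side, using the
ACF to discount correlated contributions; (3) call candidate regions as
runs of sub-threshold smoothed p-values (default seed threshold 1e-4),
merging runs separated by at most ``max_gap`` bp and never crossing a
chromosome; (4) assign each region a Stouffer-Liptak combination of its
*raw* p-values and a Sidak correction, 1 - (1 - p)^(covered/region bp), for
the number of region-sized tests the covered genome affords.

Coordinates are 0-based half-open internally (BED convention); an isolated
single-probe region spans ``[pos, pos + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PvalTrack", "make_track", "acf_estimate", "slk_smooth",
           "find_regions", "region_p", "sidak_correct", "call_dmrs"]

_P_LO, _P_HI = 1e-300, 1 - 1e-16


@dataclass
class PvalTrack:
    """Per-probe raw p-values sorted by (chromosome, position)."""

    table: pd.DataFrame  # columns: chrom, pos, probe_id, p (sorted)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "pos", "p"):
            if col not in t.columns:
                raise ValueError(f"track lacks column {col!r}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("track p-values must lie in (0, 1]")
        by_chrom = t.groupby("chrom", sort=False)["pos"]
        if not by_chrom.apply(lambda s: s.is_monotonic_increasing).all():
            raise ValueError("track must be sorted by position within chromosome")


def make_track(ewas_table: pd.DataFrame, p_col: str = "p") -> PvalTrack:
    """Build a sorted track from a per-probe association table."""
    t = ewas_table.reset_index()[["chrom", "pos", "probe_id", p_col]].rename(
        columns={p_col: "p"})
    t = t.dropna(subset=["p"])
    t["p"] = t["p"].clip(lower=_P_LO, upper=1.0)
    t = t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return PvalTrack(table=t)


def _zscores(p: np.ndarray) -> np.ndarray:
    """Probit transform: large z for small p."""
    return stats.norm.isf(np.clip(p, _P_LO, _P_HI))


def acf_estimate(track: PvalTrack, max_dist: int = 500,
                 bin_size: int = 50) -> pd.DataFrame:
    """Correlation of probit-transformed p-values by distance bin.

    Bins are left-open right-closed: (0, 50], (50, 100], ... up to
    ``max_dist``. Within each bin the Pearson correlation is computed over
    all probe pairs on the same chromosome at that separation, then clipped
    to [0, 1). Empty bins get correlation 0.
    """
    t = track.table
    z = _zscores(t["p"].to_numpy())
    edges = np.arange(0, max_dist + bin_size, bin_size)
    n_bins = len(edges) - 1
    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]

    for _, idx in t.groupby("chrom", sort=False).indices.items():
        pos = t["pos"].to_numpy()[idx]
        zz = z[idx]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(len(idx)):
            for j in range(i + 1, hi[i]):
                d = pos[j] - pos[i]
                if d <= 0:
                    continue
                b = min((d - 1) // bin_size, n_bins - 1)
                pairs_a[b].append(zz[i])
                pairs_b[b].append(zz[j])

    rows = []
    for b in range(n_bins):
        lo_edge, hi_edge = edges[b], edges[b + 1]
        n_pairs = len(pairs_a[b])
        if n_pairs >= 2:
            a = np.asarray(pairs_a[b])
            bb = np.asarray(pairs_b[b])
            if a.std() > 0 and bb.std() > 0:
                corr = float(np.corrcoef(a, bb)[0, 1])
            else:
                corr = 0.0
        else:
            corr = 0.0
        rows.append({"dist_lo": lo_edge, "dist_hi": hi_edge,
                     "corr": float(np.clip(corr, 0.0, 1 - 1e-12)),
                     "n_pairs": n_pairs})
    acf = pd.DataFrame(rows)
    if acf["n_pairs"].sum() == 0:
        import warnings
        warnings.warn("no probe pairs within max_dist; flat zero ACF")
    return acf


def _acf_lookup(acf: pd.DataFrame):
    edges = acf["dist_hi"].to_numpy()
    corrs = acf["corr"].to_numpy()

    def rho(d: np.ndarray) -> np.ndarray:
        d = np.asarray(d)
        out = np.zeros(d.shape, dtype=float)
        out[d <= 0] = 1.0  # coincident probes: perfectly correlated
        pos_mask = d > 0
        b = np.searchsorted(edges, d[pos_mask], side="left")
        b = np.clip(b, 0, len(corrs) - 1)
        vals = corrs[b]
        vals[d[pos_mask] > edges[-1]] = 0.0
        out[pos_mask] = vals
        return out

    return rho


def _stouffer_liptak(z: np.ndarray, pos: np.ndarray, rho) -> float:
    """Correlation-adjusted Stouffer combination of a set of z-scores."""
    k = z.size
    if k == 1:
        return float(z[0])
    dmat = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(k, 1)
    sum_rho = rho(dmat[iu]).sum()
    denom = np.sqrt(k + 2.0 * sum_rho)
    return float(z.sum() / denom)


def slk_smooth(track: PvalTrack, acf: pd.DataFrame,
               window: int = 500) -> pd.DataFrame:
    """Stouffer-Liptak-Kechris smoothing of the p-value track.

    For each probe, the p-values of all probes within ``window / 2`` bp on
    either side (itself included) are combined:
    ``z_comb = sum(z_j) / sqrt(k + 2 * sum_{j<l} rho(d_jl))``, and the
    smoothed p is the upper-tail normal probability of ``z_comb``. An
    isolated probe keeps its raw p; perfectly correlated identical
    neighbours add no information and also return the raw p.
    """
    t = track.table
    half = window / 2.0
    z = _zscores(t["p"].to_numpy())
    rho = _acf_lookup(acf)
    smoothed = np.empty(len(t))
    for _, idx in t.groupby("chrom", sort=False).indices.items():
        pos = t["pos"].to_numpy()[idx].astype(float)
        zz = z[idx]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for a in range(len(idx)):
            sel = slice(lo[a], hi[a])
            zc = _stouffer_liptak(zz[sel], pos[sel], rho)
            smoothed[idx[a]] = stats.norm.sf(zc)
    out = t.copy()
    out["p_smoothed"] = np.clip(smoothed, _P_LO, 1.0)
    return out


def find_regions(smoothed: pd.DataFrame, p_threshold: float = 1e-4,
                 max_gap: int = 500) -> pd.DataFrame:
    """Candidate regions: maximal runs of sub-threshold smoothed p-values.

    Consecutive sub-threshold probes are merged while the gap between them
    is at most ``max_gap`` bp; regions never span chromosomes. Returned
    intervals are 0-based half-open ``[start, end)``; a single-probe region
    spans ``[pos, pos + 1)``.
    """
    regions = []
    for chrom, grp in smoothed.groupby("chrom", sort=False):
        sub = grp[grp["p_smoothed"] < p_threshold]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        ids = list(sub.index)
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                members = ids[start_i:i]
                regions.append({
                    "chrom": chrom,
                    "start": int(pos[start_i]),
                    "end": int(pos[i - 1]) + 1,
                    "n_probes": len(members),
                    "probe_rows": members,
                })
                start_i = i
    return pd.DataFrame(regions,
                        columns=["chrom", "start", "end", "n_probes",
                                 "probe_rows"])


def region_p(raw_p: np.ndarray, positions: np.ndarray,
             acf: pd.DataFrame) -> float:
    """Stouffer-Liptak combination of the raw p-values inside a region."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        raise ValueError("empty region")
    z = _zscores(raw_p)
    zc = _stouffer_liptak(z, np.asarray(positions, dtype=float),
                          _acf_lookup(acf))
    return float(np.clip(stats.norm.sf(zc), _P_LO, 1.0))


def sidak_correct(p_region: float, region_bp: int, total_covered_bp: int) -> float:
    """Sidak multiplicity correction for a region-sized test:
    ``1 - (1 - p)^(total_covered_bp / region_bp)``."""
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    k = total_covered_bp / region_bp
    # log1p formulation keeps precision for tiny p
    return float(np.clip(-np.expm1(k * np.log1p(-min(p_region, 1 - 1e-16))),
                         _P_LO, 1.0))


def _covered_bp(track: PvalTrack, window: int) -> int:
    """Total footprint: union of +-window/2 intervals around the probes."""
    half = window // 2
    total = 0
    for _, grp in track.table.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        starts = pos - half
        ends = pos + half + 1
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return int(total)


def call_dmrs(track: PvalTrack, p_threshold: float = 1e-4, window: int = 500,
              max_gap: int = 500, max_dist: int = 500,
              bin_size: int = 50) -> pd.DataFrame:
    """Full region-calling pipeline; returns the DMR table (possibly empty)
    with region p and Sidak-corrected p per call."""
    acf = acf_estimate(track, max_dist=max_dist, bin_size=bin_size)
    smoothed = slk_smooth(track, acf, window=window)
    regions = find_regions(smoothed, p_threshold=p_threshold, max_gap=max_gap)
    if regions.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_probes",
                                     "p_region", "p_sidak"])
    total_bp = _covered_bp(track, window)
    rows = []
    for _, reg in regions.iterrows():
        members = smoothed.loc[reg["probe_rows"]]
        p_reg = region_p(members["p"].to_numpy(), members["pos"].to_numpy(), acf)
        rows.append({
            "chrom": reg["chrom"], "start": reg["start"], "end": reg["end"],
            "n_probes": reg["n_probes"], "p_region": p_reg,
            "p_sidak": sidak_correct(p_reg, reg["end"] - reg["start"], total_bp),
        })
    return pd.DataFrame(rows)
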