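"""Bead-standard normalization and palladium k-of-n debarcoding.

The normalization follows the sliding-window bead-median protocol: local
medians of the spiked normalization beads trace the instrument's sensitivity
over acquisition time, and each channel is multiplied by
``reference median / local median`` interpolated between window knots.  With
a reference shared across batches the same construction aligns batches to a
common scale.

Debarcoding rescales each palladium barcode channel to [0, 1] by its
within-run percentile range, takes the k highest channels of each event as
its preliminary code, and computes a *separation* (k-th minus (k+1)-th
rescaled intensity).  Events whose code is not in the scheme or whose
separation falls below a cutoff stay unassigned — cell-cell doublets carry
the union of two codes and therefore near-zero separation.  A per-sample
Mahalanobis-distance filter then removes events far from their assigned
sample's barcode centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .panel import BarcodeScheme, TIME_CHANNEL
from .synthetic import COFACTOR, EventMatrix

UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# bead identification
# ---------------------------------------------------------------------------

def _otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Threshold maximizing between-class variance (bimodal separator)."""
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        return np.inf
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_total = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_total * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1
    return float(centers[int(np.argmax(between))])


def identify_beads(events: EventMatrix, bead_channels: list[str] | None = None,
                   min_quantile: float = 0.95) -> np.ndarray:
    """Boolean mask of normalization-bead events.

    An event is called a bead iff *all* bead channels exceed a data-driven
    threshold separating the background and bead modes (Otsu on the
    arcsinh(x/5) scale).  If a channel shows no events above its threshold,
    a warning is raised and the mask is all-False.
    """
    if bead_channels is None:
        bead_channels = events.panel.bead_channels
    if not bead_channels:
        raise ValueError("at least one bead channel is required")
    n = events.n_events
    if n == 0:
        return np.zeros(0, dtype=bool)
    # modes closer than this on the arcsinh scale are treated as one mode
    min_separation = 1.5
    mask = np.ones(n, dtype=bool)
    for ch in bead_channels:
        z = np.arcsinh(events.data[ch].to_numpy() / COFACTOR)
        thr = _otsu_threshold(z)
        above = z > thr
        if not np.isfinite(thr) or not above.any() or above.all():
            pos = z[z > 0]
            thr = np.quantile(pos, min_quantile) if pos.size else np.inf
            above = z > thr
        sep = (z[above].mean() - z[~above].mean()) \
            if above.any() and not above.all() else 0.0
        if sep < min_separation:
            # unimodal channel: either everything is a bead (high mode) or
            # nothing is (background only)
            if np.median(z) > 2.0:
                continue          # all events carry bead signal
            warnings.warn(f"no events above bead threshold on {ch}")
            return np.zeros(n, dtype=bool)
        mask &= above
    return mask


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    """Per-channel correction multipliers at ordered time knots."""

    time_knots: np.ndarray                 # strictly increasing
    corrections: pd.DataFrame              # knots × channels, > 0
    reference: pd.Series                   # per-channel global bead median

    def __post_init__(self) -> None:
        knots = np.asarray(self.time_knots, dtype=float)
        if knots.size > 1 and not (np.diff(knots) > 0).all():
            raise ValueError("time knots must be strictly increasing")
        if (self.corrections.to_numpy() <= 0).any():
            raise ValueError("correction multipliers must be positive")
        self.time_knots = knots

    def multiplier(self, channel: str, t: np.ndarray) -> np.ndarray:
        """Interpolated correction at times t; flat beyond the knot range.

        Channels without their own bead-derived curve get the geometric mean
        of the bead-channel corrections (a global sensitivity correction).
        """
        t = np.asarray(t, dtype=float)
        if channel in self.corrections.columns:
            y = self.corrections[channel].to_numpy()
        else:
            y = np.exp(np.log(self.corrections.to_numpy()).mean(axis=1))
        if self.time_knots.size == 1:
            return np.full(t.shape, y[0])
        return np.interp(t, self.time_knots, y)


def fit_normalization(bead_events: EventMatrix, window_size: int = 500,
                      channels: list[str] | None = None,
                      reference: pd.Series | None = None
                      ) -> NormalizationFactors:
    """Sliding-window bead-median normalization factors.

    Beads are chunked into consecutive windows of ``window_size`` events
    (ordered by acquisition time); each window contributes one knot at its
    median time with correction ``reference / local median`` per channel.
    ``reference`` defaults to this run's global bead median; passing the
    pooled median across batches aligns multiple batches to a common scale.
    """
    channels = channels or bead_events.panel.bead_channels
    df = bead_events.data.sort_values(TIME_CHANNEL)
    if len(df) < window_size:
        raise ValueError(
            f"{len(df)} bead events < window_size {window_size}")
    times = df[TIME_CHANNEL].to_numpy()
    vals = df[channels].to_numpy()
    if reference is None:
        reference = pd.Series(np.median(vals, axis=0), index=channels)
    else:
        reference = reference.reindex(channels)
        if reference.isna().any():
            raise ValueError("reference lacks some channels")

    n_win = max(1, len(df) // window_size)
    knots, corr = [], []
    for w in range(n_win):
        lo = w * window_size
        hi = len(df) if w == n_win - 1 else (w + 1) * window_size
        local = np.median(vals[lo:hi], axis=0)
        for ch, m in zip(channels, local):
            if m == 0:
                raise ValueError(
                    f"zero local bead median on {ch} in window {w}")
        knots.append(float(np.median(times[lo:hi])))
        corr.append(reference.to_numpy() / local)
    return NormalizationFactors(
        time_knots=np.array(knots),
        corrections=pd.DataFrame(corr, columns=channels),
        reference=reference,
    )


def pooled_bead_reference(bead_runs: list[EventMatrix],
                          channels: list[str] | None = None) -> pd.Series:
    """Global bead median across several batches (shared reference)."""
    channels = channels or bead_runs[0].panel.bead_channels
    allv = np.vstack([r.data[channels].to_numpy() for r in bead_runs])
    return pd.Series(np.median(allv, axis=0), index=channels)


def apply_normalization(events: EventMatrix, factors: NormalizationFactors
                        ) -> EventMatrix:
    """Multiply every measurement channel by its time-interpolated correction."""
    missing = [c for c in factors.corrections.columns
               if c not in events.data.columns]
    if missing:
        raise ValueError(f"events lack normalization channels {missing}")
    out = events.copy()
    t = out.data[TIME_CHANNEL].to_numpy()
    for ch in events.panel.measurement_channels:
        out.data[ch] = out.data[ch].to_numpy() * factors.multiplier(ch, t)
    return out


# ---------------------------------------------------------------------------
# debarcoding
# ---------------------------------------------------------------------------

@dataclass
class BarcodeAssignment:
    """Per-event assignment with separation and Mahalanobis distance."""

    table: pd.DataFrame      # columns: sample_id, separation, mahalanobis, reason
    rescaled: np.ndarray = field(repr=False, default=None)

    @property
    def sample_id(self) -> pd.Series:
        return self.table["sample_id"]

    @property
    def assigned(self) -> np.ndarray:
        return (self.table["sample_id"] != UNASSIGNED).to_numpy()


def _rescale_barcodes(events: EventMatrix, scheme: BarcodeScheme,
                      lo_q: float = 0.01, hi_q: float = 0.99) -> np.ndarray:
    """arcsinh-transform and percentile-rescale barcode channels to [0, 1]."""
    chans = events.panel.barcode_channels
    if len(chans) != scheme.n:
        raise ValueError(
            f"panel has {len(chans)} barcode channels, scheme expects {scheme.n}")
    z = np.arcsinh(events.data[chans].to_numpy() / COFACTOR)
    lo = np.quantile(z, lo_q, axis=0)
    hi = np.quantile(z, hi_q, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((z - lo) / span, 0.0, 1.0)


def assign_barcodes(events: EventMatrix, scheme: BarcodeScheme,
                    separation_cutoff: float = 0.3) -> BarcodeAssignment:
    """Preliminary k-of-n assignment by top-k barcode channels.

    Per event: rescale channels, sort intensities, separation = k-th highest
    minus (k+1)-th highest; the indicator of the k highest channels is looked
    up in the scheme.  Unassigned reasons: ``low_separation`` (below cutoff,
    e.g. doublets) or ``bad_code`` (code not in scheme).
    """
    r = _rescale_barcodes(events, scheme)
    n_ev = r.shape[0]
    k = scheme.k
    order = np.argsort(r, axis=1)
    sorted_r = np.take_along_axis(r, order, axis=1)
    separation = sorted_r[:, -k] - sorted_r[:, -(k + 1)] if n_ev else \
        np.zeros(0)

    code_bits = np.zeros((n_ev, scheme.n), dtype=int)
    if n_ev:
        top = order[:, -k:]
        np.put_along_axis(code_bits, top, 1, axis=1)
    weights = 1 << np.arange(scheme.n)
    keys = code_bits @ weights
    lut = {int(np.array(c) @ weights): sid for sid, c in scheme.codes.items()}

    sample = np.array([lut.get(int(key), UNASSIGNED) for key in keys],
                      dtype=object)
    reason = np.where(sample == UNASSIGNED, "bad_code", "")
    low = separation < separation_cutoff
    sample[low] = UNASSIGNED
    reason = np.where(low, "low_separation", reason)

    table = pd.DataFrame({
        "sample_id": sample,
        "separation": separation,
        "mahalanobis": np.nan,
        "reason": reason,
    })
    return BarcodeAssignment(table=table, rescaled=r)


def mahalanobis_filter(events: EventMatrix, assignment: BarcodeAssignment,
                       scheme: BarcodeScheme, max_dist: float = 30.0,
                       squared: bool = True) -> BarcodeAssignment:
    """Remove events far from their assigned sample's barcode centroid.

    Distances are computed on the rescaled barcode channels from the
    preliminary assignment (single pass, no iteration).  By default the
    *squared* Mahalanobis distance is compared against ``max_dist``; set
    ``squared=False`` to threshold the plain distance.  Samples with too few
    events to estimate a covariance are skipped with a warning; singular
    covariances are ridge-regularized.
    """
    r = assignment.rescaled if assignment.rescaled is not None else \
        _rescale_barcodes(events, scheme)
    table = assignment.table.copy()
    sample = table["sample_id"].to_numpy(dtype=object, copy=True)
    reason = table["reason"].to_numpy(dtype=object, copy=True)
    dist = table["mahalanobis"].to_numpy(copy=True)

    for sid in scheme.sample_ids:
        idx = np.flatnonzero(sample == sid)
        if idx.size == 0:
            continue
        if idx.size < scheme.n + 1:
            warnings.warn(
                f"{sid}: {idx.size} events < {scheme.n + 1}; "
                "skipping Mahalanobis filter")
            continue
        x = r[idx]
        # deterministic robust estimate: median/MAD pre-screen, then
        # classical mean/covariance on the inliers — a handful of foreign-code
        # events would otherwise inflate the covariance along their own
        # direction and slip under the threshold
        med = np.median(x, axis=0)
        scale = 1.4826 * np.median(np.abs(x - med), axis=0)
        fallback = x.std(axis=0)
        scale = np.where(scale > 0, scale,
                         np.where(fallback > 0, fallback, 1.0))
        d0 = (((x - med) / scale) ** 2).sum(axis=1)
        inlier = d0 <= chi2.ppf(0.99, scheme.n)
        if inlier.sum() < scheme.n + 1:
            inlier = np.ones(len(x), dtype=bool)
        mu = x[inlier].mean(axis=0)
        cov = np.cov(x[inlier], rowvar=False)
        eps = 1e-6 * float(np.mean(np.diag(cov)))
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"{sid}: singular barcode covariance; regularizing")
            inv = np.linalg.inv(cov + max(eps, 1e-12) * np.eye(scheme.n))
        d = x - mu
        d2 = np.einsum("ij,jk,ik->i", d, inv, d)
        d2 = np.maximum(d2, 0.0)
        val = d2 if squared else np.sqrt(d2)
        dist[idx] = val
        drop = idx[val > max_dist]
        sample[drop] = UNASSIGNED
        reason[drop] = "distance"
        dist[drop] = np.nan

    table["sample_id"] = sample
    table["reason"] = reason
    table["mahalanobis"] = dist
    return BarcodeAssignment(table=table, rescaled=r)


@dataclass
class DebarcodeResult:
    samples: dict[str, EventMatrix]
    assignment: BarcodeAssignment
    yield_report: pd.DataFrame


def debarcode(events: EventMatrix, scheme: BarcodeScheme,
              separation_cutoff: float = 0.3, max_dist: float = 30.0,
              squared: bool = True) -> DebarcodeResult:
    """Full debarcoding: assign, Mahalanobis-filter, split into samples.

    The outputs are a disjoint partition of the assigned events; the yield
    report counts assigned events per sample and unassigned events by reason.
    """
    prelim = assign_barcodes(events, scheme, separation_cutoff)
    final = mahalanobis_filter(events, prelim, scheme, max_dist, squared)
    sid = final.table["sample_id"].to_numpy()

    samples: dict[str, EventMatrix] = {}
    for s in scheme.sample_ids:
        idx = np.flatnonzero(sid == s)
        data = events.data.iloc[idx].reset_index(drop=True)
        truth = events.truth.iloc[idx].reset_index(drop=True) \
            if events.truth is not None else None
        samples[s] = EventMatrix(data, events.panel, truth)

    rows = [{"sample_id": s, "count": int((sid == s).sum()), "status": "assigned"}
            for s in scheme.sample_ids]
    un = final.table[sid == UNASSIGNED]
    for reason, cnt in un["reason"].value_counts().items():
        rows.append({"sample_id": UNASSIGNED, "count": int(cnt),
                     "status": reason})
    report = pd.DataFrame(rows, columns=["sample_id", "count", "status"])
    report["fraction"] = report["count"] / max(1, len(final.table))
    return DebarcodeResult(samples=samples, assignment=final,
                           yield_report=report)
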