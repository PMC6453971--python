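"""Recombination analysis on a genome multiple alignment.

Two complementary views:

* A phylogenetic compatibility matrix: neighbor-joining trees (TN93
  distances) are built in sliding windows (default 300 nt window, 100 nt
  step) and every window pair is scored by the normalized
  Robinson-Foulds distance between the two trees — 0 when the windows
  support identical topologies, 1 when they share no internal split.
  Recombination shows up as block structure.

* A breakpoint-density profile: given a list of breakpoint positions
  (from any detector), breakpoints are counted in a sliding window
  (default 400 nt, 1 nt step) and compared against permutation envelopes
  obtained by redistributing the same number of breakpoints uniformly
  over the alignment (default 1,000 permutations; 95% and 99% two-sided
  envelopes).  Hot spots are maximal runs where the observed count
  strictly exceeds the 99% upper envelope; cold spots where it falls
  strictly below the 95% lower envelope.

A simple maximum chi-square triplet scanner is provided as plumbing to
propose breakpoints when no external detector output is available; it is
deliberately minimal and permutation-calibrated (p < 0.01).
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .phylo import (
    DistanceMatrix,
    MultipleAlignment,
    UnrootedTree,
    nj_tree,
    normalized_rf,
    tn93_matrix,
)


# ---------------------------------------------------------------------------
# compatibility matrix


@dataclass(frozen=True)
class CompatibilityConfig:
    window: int = 300
    step: int = 100
    tn93_ceiling: float = 5.0


@dataclass(frozen=True)
class CompatibilityMatrix:
    window_starts: tuple[int, ...]
    values: np.ndarray               # symmetric, zero diagonal, NaN = masked
    config: CompatibilityConfig
    masked: tuple[int, ...] = ()     # indices of windows whose tree failed

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(str(s) for s in self.window_starts) + "\n")
            for s, row in zip(self.window_starts, self.values):
                fh.write(
                    str(s) + "\t"
                    + "\t".join("" if np.isnan(x) else f"{x:.4f}" for x in row)
                    + "\n"
                )


def window_starts(L: int, window: int, step: int) -> list[int]:
    """Window start positions: 0, step, 2*step, ... with a final window
    right-aligned to end exactly at L when the stride would truncate."""
    if not 0 < window <= L:
        raise ValueError("window must be in (0, L]")
    if step <= 0:
        raise ValueError("step must be positive")
    starts = list(range(0, L - window + 1, step))
    if starts[-1] + window < L:
        starts.append(L - window)
    return starts


def compatibility_matrix(
    aln: MultipleAlignment, cfg: CompatibilityConfig | None = None
) -> CompatibilityMatrix:
    """Window-by-window normalized RF distances over the alignment.

    Windows whose distance matrix cannot be computed (no comparable
    columns) are masked (NaN row/column) rather than aborting the scan;
    saturated pairwise distances are replaced by the configured ceiling
    inside the window.
    """
    cfg = cfg or CompatibilityConfig()
    if aln.n < 4:
        raise ValueError("need at least 4 taxa for a compatibility matrix")
    starts = window_starts(aln.length, cfg.window, cfg.step)
    trees: list[UnrootedTree | None] = []
    for s in starts:
        try:
            D = tn93_matrix(aln.window(s, s + cfg.window), cfg.tn93_ceiling)
            trees.append(nj_tree(D))
        except ValueError:
            trees.append(None)
    k = len(starts)
    vals = np.zeros((k, k))
    masked = tuple(i for i, t in enumerate(trees) if t is None)
    for i in masked:
        vals[i, :] = np.nan
        vals[:, i] = np.nan
    for i, j in itertools.combinations(range(k), 2):
        if trees[i] is None or trees[j] is None:
            continue
        v = normalized_rf(trees[i], trees[j])
        vals[i, j] = vals[j, i] = v
    for i in range(k):
        if i not in masked:
            vals[i, i] = 0.0
    return CompatibilityMatrix(tuple(starts), vals, cfg, masked)


# ---------------------------------------------------------------------------
# breakpoint density profile


@dataclass(frozen=True)
class BreakpointConfig:
    window: int = 400
    step: int = 1
    n_perm: int = 1000
    seed: int = 1


@dataclass(frozen=True)
class BreakpointProfile:
    positions: np.ndarray     # window centers
    observed: np.ndarray      # breakpoint count per window
    env95: tuple[np.ndarray, np.ndarray]   # (lower, upper)
    env99: tuple[np.ndarray, np.ndarray]
    hot: tuple[tuple[int, int], ...]       # inclusive center-coordinate runs
    cold: tuple[tuple[int, int], ...]
    config: BreakpointConfig

    def write_tsv(self, path) -> None:
        hotmask = _runs_to_mask(self.hot, self.positions)
        coldmask = _runs_to_mask(self.cold, self.positions)
        with open(path, "w") as fh:
            fh.write(
                "position\tobserved\tenv95_lo\tenv95_hi\tenv99_lo\tenv99_hi\thot\tcold\n"
            )
            for k in range(len(self.positions)):
                fh.write(
                    f"{self.positions[k]}\t{self.observed[k]}\t"
                    f"{self.env95[0][k]}\t{self.env95[1][k]}\t"
                    f"{self.env99[0][k]}\t{self.env99[1][k]}\t"
                    f"{int(hotmask[k])}\t{int(coldmask[k])}\n"
                )


def _runs_to_mask(runs, positions) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for a, b in runs:
        mask |= (positions >= a) & (positions <= b)
    return mask


def _mask_to_runs(mask: np.ndarray, positions: np.ndarray) -> tuple[tuple[int, int], ...]:
    runs = []
    start = None
    for k, m in enumerate(mask):
        if m and start is None:
            start = k
        elif not m and start is not None:
            runs.append((int(positions[start]), int(positions[k - 1])))
            start = None
    if start is not None:
        runs.append((int(positions[start]), int(positions[-1])))
    return tuple(runs)


def _window_counts(positions: np.ndarray, L: int, window: int) -> np.ndarray:
    """Counts of points inside [x, x+window) for every start x in
    [0, L-window]; vectorized over rows when ``positions`` is 2-D."""
    pos = np.atleast_2d(positions)
    n_rows = pos.shape[0]
    flat = (pos + (np.arange(n_rows)[:, None] * L)).ravel()
    hist = np.bincount(flat, minlength=n_rows * L).reshape(n_rows, L)
    csum = np.concatenate(
        [np.zeros((n_rows, 1), dtype=np.int64), np.cumsum(hist, axis=1)], axis=1
    )
    out = csum[:, window:] - csum[:, :-window]
    return out if positions.ndim == 2 else out[0]


def _envelope_indices(n_perm: int, level: float) -> tuple[int, int]:
    """Order-statistic indices for a two-sided envelope at the given
    level, with the (k+1) finite-sample correction."""
    alpha = 1.0 - level / 100.0
    lo = max(math.ceil((alpha / 2) * (n_perm + 1)) - 1, 0)
    hi = min(math.ceil((1 - alpha / 2) * (n_perm + 1)) - 1, n_perm - 1)
    return lo, hi


def breakpoint_profile(
    breakpoints,
    L: int,
    cfg: BreakpointConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BreakpointProfile:
    """Sliding-window breakpoint density with permutation envelopes.

    The null redistributes the same number of breakpoints uniformly at
    random over [0, L); per-window two-sided 95% and 99% envelopes are
    order statistics of the permutation counts.  Hot: observed strictly
    above the 99% upper envelope; cold: strictly below the 95% lower
    envelope; both reported as maximal runs of window centers.  An empty
    breakpoint list yields an all-zero profile with no calls.
    """
    cfg = cfg or BreakpointConfig()
    if cfg.window > L:
        raise ValueError("window exceeds sequence length")
    if cfg.n_perm < 1:
        raise ValueError("need at least one permutation")
    bps = np.asarray(sorted(int(b) for b in breakpoints), dtype=np.int64)
    if bps.size and (bps.min() < 0 or bps.max() >= L):
        raise ValueError("breakpoint position outside [0, L)")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    starts = np.arange(0, L - cfg.window + 1, cfg.step)
    centers = starts + cfg.window // 2
    if bps.size == 0:
        z = np.zeros(len(starts), dtype=np.int64)
        return BreakpointProfile(centers, z, (z, z), (z, z), (), (), cfg)
    observed = _window_counts(bps, L, cfg.window)[:: cfg.step]
    perm_pos = rng.integers(0, L, size=(cfg.n_perm, bps.size))
    perm_counts = _window_counts(perm_pos, L, cfg.window)[:, :: cfg.step]
    perm_sorted = np.sort(perm_counts, axis=0)
    lo95, hi95 = _envelope_indices(cfg.n_perm, 95.0)
    lo99, hi99 = _envelope_indices(cfg.n_perm, 99.0)
    env95 = (perm_sorted[lo95], perm_sorted[hi95])
    env99 = (perm_sorted[lo99], perm_sorted[hi99])
    hot = _mask_to_runs(observed > env99[1], centers)
    cold = _mask_to_runs(observed < env95[0], centers)
    return BreakpointProfile(centers, observed, env95, env99, hot, cold, cfg)


# ---------------------------------------------------------------------------
# convenience breakpoint detector (maximum chi-square triplet scan)


@dataclass(frozen=True)
class BreakpointCall:
    position: int                    # alignment column
    triplet: tuple[str, str, str]    # (recombinant, parent A, parent B)
    chi2: float
    p_value: float


def _max_chi2(labels01: np.ndarray) -> tuple[float, int]:
    """Maximum over all cut points of the 2x2 chi-square contrasting
    parent-A/parent-B matches left vs right of the cut."""
    m = labels01.size
    ones = np.cumsum(labels01)
    total1 = ones[-1]
    k = np.arange(1, m)              # size of left part
    left1 = ones[:-1]
    left0 = k - left1
    right1 = total1 - left1
    right0 = (m - k) - right1
    # chi-square for 2x2 tables, guarding empty margins
    nL, nR = k, m - k
    c1, c0 = total1, m - total1
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack(
            [nL * c0 / m, nL * c1 / m, nR * c0 / m, nR * c1 / m]
        )
        obs = np.stack([left0, left1, right0, right1])
        chi = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    if c1 == 0 or c0 == 0:
        return 0.0, m // 2
    best = int(np.argmax(chi))
    return float(chi[best]), best + 1


def naive_breakpoint_detector(
    aln: MultipleAlignment,
    rng: np.random.Generator | int = 1,
    max_triplets: int = 30,
    n_perm: int = 199,
    alpha: float = 0.01,
) -> list[BreakpointCall]:
    """Propose breakpoints by a maximum chi-square scan over informative
    sites of sampled (recombinant, parentA, parentB) triplets.

    For each triplet, informative sites are columns where the two parents
    differ and the candidate recombinant matches exactly one of them; the
    best cut point of the match pattern is scored by a 2x2 chi-square and
    calibrated by permuting the pattern (p < ``alpha`` required).  One
    call at most per triplet.  This is plumbing for
    :func:`breakpoint_profile`, not a full recombination detector.
    """
    if aln.n < 3:
        raise ValueError("need at least 3 rows")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    trip_idx = list(itertools.combinations(range(aln.n), 3))
    if len(trip_idx) > max_triplets:
        pick = rng.choice(len(trip_idx), size=max_triplets, replace=False)
        trip_idx = [trip_idx[i] for i in sorted(pick)]
    enc = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    calls: list[BreakpointCall] = []
    for t in trip_idx:
        best_call = None
        for r_pos in range(3):
            r = t[r_pos]
            a, b = (x for x in t if x != r)
            ra, rb, rr = enc[a], enc[b], enc[r]
            informative = (ra != rb) & ((rr == ra) | (rr == rb))
            cols = np.flatnonzero(informative)
            if cols.size < 4:
                continue
            pattern = (rr[cols] == rb[cols]).astype(np.int64)
            chi_obs, cut = _max_chi2(pattern)
            if chi_obs <= 0:
                continue
            perm_stats = np.empty(n_perm)
            for k in range(n_perm):
                perm_stats[k] = _max_chi2(rng.permutation(pattern))[0]
            p = (1 + int(np.sum(perm_stats >= chi_obs))) / (n_perm + 1)
            if p < alpha:
                pos = int((cols[cut - 1] + cols[cut]) // 2)
                call = BreakpointCall(
                    pos,
                    (aln.labels[r], aln.labels[a], aln.labels[b]),
                    chi_obs,
                    p,
                )
                if best_call is None or call.chi2 > best_call.chi2:
                    best_call = call
        if best_call is not None:
            calls.append(best_call)
    return calls


# ---------------------------------------------------------------------------
# rendering


def render_outputs(
    cm: CompatibilityMatrix | None,
    bp: BreakpointProfile | None,
    out_dir,
    basename: str = "recombination",
) -> list[str]:
    """Write machine-readable TSVs and figures for the two analyses.

    Returns the list of files written.  TSV content is deterministic for
    a fixed seed and inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written = []
    if cm is not None:
        tsv = os.path.join(out_dir, f"{basename}_compatibility.tsv")
        cm.write_tsv(tsv)
        written.append(tsv)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(
            cm.values, origin="lower", cmap="viridis", vmin=0, vmax=1,
            extent=[
                cm.window_starts[0], cm.window_starts[-1] + cm.config.window,
                cm.window_starts[0], cm.window_starts[-1] + cm.config.window,
            ],
        )
        fig.colorbar(im, ax=ax, label="normalized RF distance")
        ax.set_xlabel("alignment position (nt)")
        ax.set_ylabel("alignment position (nt)")
        ax.set_title("Phylogenetic compatibility matrix")
        png = os.path.join(out_dir, f"{basename}_compatibility.png")
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    if bp is not None:
        tsv = os.path.join(out_dir, f"{basename}_breakpoints.tsv")
        bp.write_tsv(tsv)
        written.append(tsv)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(bp.positions, bp.env95[0], bp.env95[1],
                        color="0.8", label="95% envelope")
        ax.fill_between(bp.positions, bp.env99[0], bp.env99[1],
                        color="mistyrose", alpha=0.6, label="99% envelope")
        ax.plot(bp.positions, bp.observed, "k-", lw=1, label="observed")
        for a, b in bp.hot:
            ax.axvspan(a, b, color="red", alpha=0.2)
        for a, b in bp.cold:
            ax.axvspan(a, b, color="blue", alpha=0.15)
        ax.set_xlabel("alignment position (window center, nt)")
        ax.set_ylabel("breakpoints per window")
        ax.set_title("Recombination breakpoint distribution")
        ax.legend(loc="upper right", fontsize=8)
        png = os.path.join(out_dir, f"{basename}_breakpoints.png")
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    return written


def read_breakpoints_tsv(path) -> list[int]:
    """Breakpoint positions from a TSV with a ``position`` column (header
    optional; extra columns such as provenance are ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            first = line.split("\t")[0]
            if first.lower() == "position":
                continue
            out.append(int(first))
    return out
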