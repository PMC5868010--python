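"""Non-negative matrix factorization of time-resolved diagonal slices.

The kinetics matrix I (time x frequency) is factored as I^T = W H + U with
W >= 0 the vibrational eigenspectra (frequency x rank), H >= 0 the
time-dependent intensities (rank x time) and U the residual.  Factorization
uses the Frobenius multiplicative-update iteration with a configurable
number of independently seeded random restarts (replicates; 16 by default),
keeping the replicate with the smallest residual.  The number of kinetic
states is selected by null-vector detection: when the requested rank exceeds
the number of distinct states, a component with negligible energy appears.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "KineticsDataset",
    "FactorResult",
    "RankDiagnostics",
    "factorize",
    "select_rank",
    "restrict_band",
    "match_components",
    "dataset_from_slices",
]

_EPS = 1e-12


@dataclass
class KineticsDataset:
    """Time-resolved spectral intensities: rows = time points (minutes,
    ascending), columns = frequency grid (cm^-1).

    ``sign_flipped`` records that a negative-going sequence-band slice was
    negated to make the matrix non-negative; ``window`` records any band
    restriction applied by :func:`restrict_band`.
    """

    times: np.ndarray
    grid: np.ndarray
    intensity: np.ndarray
    sign_flipped: bool = False
    window: tuple = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.grid = np.asarray(self.grid, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.intensity.shape != (len(self.times), len(self.grid)):
            raise ValueError("intensity matrix shape mismatch")

    def save(self, path) -> None:
        """Delimited text: first row = frequency grid, first column = time."""
        with open(path, "w") as fh:
            fh.write("t_min\t" + "\t".join(f"{w:.6f}" for w in self.grid) + "\n")
            for t, row in zip(self.times, self.intensity):
                fh.write(f"{t:.6f}\t" + "\t".join(f"{v:.8e}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "KineticsDataset":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        grid = np.array([float(x) for x in lines[0].split("\t")[1:]])
        times, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        return cls(times=np.array(times), grid=grid, intensity=np.array(rows))


def dataset_from_slices(slices, times) -> KineticsDataset:
    """Stack diagonal slices (one per time point) into a KineticsDataset.

    Sequence-band slices are negated (not absolute-valued) so the matrix is
    non-negative; the flip is recorded in ``sign_flipped``.
    """
    if len(slices) != len(times):
        raise ValueError("one slice per time point required")
    bands = {s.band for s in slices}
    if len(bands) != 1:
        raise ValueError("slices mix bands")
    band = bands.pop()
    grid = slices[0].grid
    for s in slices[1:]:
        if not np.array_equal(s.grid, grid):
            raise ValueError("slices on different grids")
    I = np.vstack([s.intensity for s in slices])
    flipped = band == "sequence"
    if flipped:
        I = -I
    return KineticsDataset(times=np.asarray(times, float), grid=grid.copy(),
                           intensity=np.clip(I, 0.0, None),
                           sign_flipped=flipped)


@dataclass
class FactorResult:
    """Best-of-replicates NNMF factors of one dataset.

    ``W``: frequency x rank eigenspectra; ``H``: rank x time intensities;
    ``U = I^T - W H`` the residual; ``objective = ||U||_F``.
    """

    W: np.ndarray
    H: np.ndarray
    U: np.ndarray
    objective: float
    rank: int
    replicate_seeds: list
    chosen_replicate: int
    objective_history: np.ndarray
    n_iter: int

    def component_energies(self) -> np.ndarray:
        """Energy ||W_k||_2 * ||H_k||_2 of each component."""
        return (np.linalg.norm(self.W, axis=0)
                * np.linalg.norm(self.H, axis=1))

    def component_redundancy(self) -> np.ndarray:
        """Pairwise joint cosine similarity of components.

        Entry (k, j) is cos(W_k, W_j) * cos(H_k, H_j); a pair close to 1
        is two copies of one kinetic state, so the factorization carries
        fewer unique states than its nominal rank.
        """
        Wn = self.W / (np.linalg.norm(self.W, axis=0, keepdims=True) + _EPS)
        Hn = self.H / (np.linalg.norm(self.H, axis=1, keepdims=True) + _EPS)
        return (Wn.T @ Wn) * (Hn @ Hn.T)

    def save(self, w_path, h_path, meta_path=None, extra_meta=None) -> None:
        np.savetxt(w_path, self.W, delimiter="\t", fmt="%.8e")
        np.savetxt(h_path, self.H, delimiter="\t", fmt="%.8e")
        if meta_path is not None:
            import json
            meta = {
                "rank": int(self.rank),
                "objective": float(self.objective),
                "replicate_seeds": [int(s) for s in self.replicate_seeds],
                "chosen_replicate": int(self.chosen_replicate),
                "n_iter": int(self.n_iter),
            }
            if extra_meta:
                meta.update(extra_meta)
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")


def _mu_factorize(X, rank, rng, max_iter, tol):
    """Single multiplicative-update run; returns (W, H, history, n_iter)."""
    nf, nt = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / rank)
    W = rng.uniform(0.0, 1.0, (nf, rank)) * scale
    H = rng.uniform(0.0, 1.0, (rank, nt)) * scale
    norm_x = np.linalg.norm(X)
    history = []
    prev = None
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = np.linalg.norm(X - W @ H)
        history.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(norm_x, _EPS):
            break
        prev = obj
    return W, H, np.array(history), it


def factorize(data: KineticsDataset, rank: int, replicates: int = 16,
              max_iter: int = 5000, tol: float = 1e-8,
              seed: int = 0) -> FactorResult:
    """Best-of-``replicates`` multiplicative-update NNMF at fixed rank.

    Each replicate starts from an independent uniform(0, 1) initialization
    scaled to the data mean, with per-replicate seeds spawned from ``seed``;
    the replicate with the smallest Frobenius residual wins.  Iteration
    stops at ``max_iter`` or when the objective changes by less than
    ``tol * ||I||_F`` between iterations.
    """
    I = data.intensity
    if np.any(I < 0):
        raise ValueError(
            "negative entries in the kinetics matrix; sequence-band slices "
            "must be sign-corrected first (see KineticsDataset.sign_flipped)")
    lo = min(I.shape)
    if not 1 <= rank <= lo:
        raise ValueError(f"rank must be in 1..{lo}, got {rank}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    X = I.T  # frequency x time
    children = np.random.SeedSequence(seed).spawn(replicates)
    rep_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    best = None
    for r, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        W, H, hist, n_iter = _mu_factorize(X, rank, rng, max_iter, tol)
        obj = hist[-1]
        if best is None or obj < best[0]:
            best = (obj, r, W, H, hist, n_iter)
    obj, r, W, H, hist, n_iter = best
    U = X - W @ H
    return FactorResult(W=W, H=H, U=U, objective=float(obj), rank=rank,
                        replicate_seeds=rep_seeds, chosen_replicate=r,
                        objective_history=hist, n_iter=n_iter)


@dataclass
class RankDiagnostics:
    """Per-rank diagnostics from :func:`select_rank`."""

    rank: int
    objective: float
    energies: np.ndarray
    null_components: list
    max_redundancy: float = 0.0


def select_rank(data: KineticsDataset, rank_range=(1, 4),
                null_threshold: float = 0.02, replicates: int = 16,
                max_iter: int = 5000, tol: float = 1e-8, seed: int = 0,
                redundancy_threshold: float = 0.35):
    """Choose the number of kinetic states by null-vector detection.

    For each rank in ``rank_range`` (inclusive) the dataset is factorized
    and components carrying no unique kinetic state are flagged as null:
    either their energy falls below ``null_threshold`` times the dominant
    component's energy, or they duplicate another component (joint
    spectrum-and-time-course cosine above ``redundancy_threshold``; the
    lower-energy member of the pair is flagged).  The best-of-replicates
    multiplicative update fills an excess rank with either a dying
    component or two copies of one state, and both signatures mean the
    same thing: fewer unique states than the nominal rank.  The effective
    rank is the largest rank with no null component.  Returns
    ``(effective_rank, [RankDiagnostics, ...])``.
    """
    lo, hi = rank_range
    if not 1 <= lo <= hi <= min(data.intensity.shape):
        raise ValueError(f"invalid rank range {rank_range}")
    diags = []
    effective = None
    for r in range(lo, hi + 1):
        res = factorize(data, r, replicates=replicates, max_iter=max_iter,
                        tol=tol, seed=seed)
        en = res.component_energies()
        nulls = set(np.flatnonzero(en < null_threshold * en.max()))
        J = res.component_redundancy()
        max_red = 0.0
        for k in range(r):
            for j in range(k + 1, r):
                max_red = max(max_red, J[k, j])
                if J[k, j] > redundancy_threshold:
                    nulls.add(j if en[j] <= en[k] else k)
        diags.append(RankDiagnostics(rank=r, objective=res.objective,
                                     energies=en,
                                     null_components=sorted(nulls),
                                     max_redundancy=float(max_red)))
        if not nulls:
            effective = r
    return effective, diags


def restrict_band(data: KineticsDataset, window) -> KineticsDataset:
    """Keep only frequency columns with lo <= w < hi.

    ``window = (lo, hi)``; use ``-np.inf`` / ``np.inf`` for open ends.  The
    applied window is recorded on the returned dataset.
    """
    lo, hi = window
    keep = (data.grid >= lo) & (data.grid < hi)
    if not np.any(keep):
        raise ValueError(f"window {window} does not overlap the grid "
                         f"[{data.grid[0]}, {data.grid[-1]}]")
    return KineticsDataset(times=data.times.copy(), grid=data.grid[keep],
                           intensity=data.intensity[:, keep],
                           sign_flipped=data.sign_flipped,
                           window=(float(lo), float(hi)))


def match_components(W_true: np.ndarray, W_est: np.ndarray):
    """Optimal column matching between two spectra matrices.

    Returns ``(perm, cosines)`` where ``W_est[:, perm[k]]`` is the match of
    ``W_true[:, k]`` and ``cosines[k]`` the cosine similarity of the pair.
    NNMF factors are only identified up to component permutation and scale,
    so recovered components must be compared this way.
    """
    a = W_true / (np.linalg.norm(W_true, axis=0, keepdims=True) + _EPS)
    b = W_est / (np.linalg.norm(W_est, axis=0, keepdims=True) + _EPS)
    sim = a.T @ b
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]
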