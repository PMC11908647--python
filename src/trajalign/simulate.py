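"""Synthetic trajectory pairs with known ground-truth alignment.

The generator emulates the geometry of developmental scRNA-seq pairs without
simulating a regulatory network: each gene follows a smooth pulse program
over a latent process time in [0, 1], with program centers ordered along the
axis so genes switch on sequentially. Counts are drawn from a negative
binomial around the program mean and log1p-transformed; observed pseudotime
is a mildly distorted, jittered copy of latent time rescaled to [0, 1], so
trajectory inference itself stays out of the loop.

Three pair geometries are available:

truncated
    Both conditions run the same program, but condition B's latent time
    stops at a fraction ``tau`` of A's axis — a knockout arrested partway
    through development.
diverge_converge
    Shared programs outside a latent interval [d1, d2]; inside it each
    condition activates its own disjoint set of pulse genes, so the middle
    sections of the processes are genuinely different.
negative_control
    Independently drawn program orders and shapes per condition: no shared
    process at all.

Pulse programs use a smooth compactly supported bump, which makes the
"identical outside [d1, d2]" guarantee of the diverge-converge geometry
exact rather than approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from trajalign.io import TrajectoryData

#: Default pulse half-width on the latent [0, 1] axis.
DEFAULT_PULSE_HALFWIDTH = 0.18
#: Default pulse amplitude (mean counts at the pulse peak).
DEFAULT_AMPLITUDE = 6.0
#: Default negative-binomial size (inverse-dispersion) parameter.
DEFAULT_NB_SIZE = 15.0
#: Default pseudotime jitter amplitude (latent-time units).
DEFAULT_PT_JITTER = 0.02

GEOMETRIES = ("truncated", "diverge_converge", "negative_control")


@dataclass
class SyntheticPair:
    """A simulated two-condition trajectory pair with its ground truth."""

    trajectory_a: TrajectoryData
    trajectory_b: TrajectoryData
    geometry: str
    truth: dict = field(default_factory=dict)
    seed: int = 0
    latent_a: np.ndarray = field(repr=False, default=None)
    latent_b: np.ndarray = field(repr=False, default=None)


def _bump(z: np.ndarray) -> np.ndarray:
    """Smooth bump with support (-1, 1): exp(1 - 1/(1 - z^2))."""
    out = np.zeros_like(z)
    inside = np.abs(z) < 1
    zi = z[inside]
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - zi**2))
    return out


def _program_means(
    t: np.ndarray,
    centers: np.ndarray,
    halfwidths: np.ndarray,
    amplitudes: np.ndarray,
    baselines: np.ndarray,
) -> np.ndarray:
    """Mean counts, gene by cell, of pulse programs evaluated at ``t``."""
    z = (t[None, :] - centers[:, None]) / halfwidths[:, None]
    return baselines[:, None] + amplitudes[:, None] * _bump(z)


def _observe(
    rng: np.random.Generator,
    t: np.ndarray,
    means: np.ndarray,
    nb_size: float,
    pt_jitter: float,
) -> tuple[np.ndarray, np.ndarray]:
    """NB counts -> log1p expression, plus observed pseudotime in [0, 1]."""
    p_nb = nb_size / (nb_size + means)
    counts = rng.negative_binomial(nb_size, p_nb)
    expression = np.log1p(counts.astype(float))
    gamma = rng.uniform(0.9, 1.1)
    span = t.max() - t.min()
    latent01 = (t - t.min()) / span if span > 0 else t * 0
    pt = latent01**gamma + rng.uniform(-pt_jitter, pt_jitter, size=t.shape)
    pt = (pt - pt.min()) / (pt.max() - pt.min())
    return expression, pt


def simulate_pair(
    geometry: str,
    n_cells: int = 300,
    n_genes: int = 50,
    seed: int = 0,
    tau: float = 0.6,
    diverge_interval: tuple = (0.4, 0.7),
    pulse_halfwidth: float = DEFAULT_PULSE_HALFWIDTH,
    amplitude: float = DEFAULT_AMPLITUDE,
    nb_size: float = DEFAULT_NB_SIZE,
    pt_jitter: float = DEFAULT_PT_JITTER,
) -> SyntheticPair:
    """Simulate one two-condition trajectory pair.

    Parameters
    ----------
    geometry
        ``"truncated"``, ``"diverge_converge"`` or ``"negative_control"``.
    n_cells, n_genes
        Cells per condition and genes (shared across conditions).
    tau
        Truncation fraction for the truncated geometry, in (0, 1).
    diverge_interval
        Latent interval [d1, d2] of divergent programs for diverge_converge.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")
    rng = np.random.default_rng(seed)
    h = pulse_halfwidth

    t_a = np.sort(rng.uniform(0.0, 1.0, n_cells))
    baselines = rng.uniform(0.05, 0.3, n_genes)
    amplitudes = amplitude * rng.uniform(0.7, 1.3, n_genes)
    halfwidths = np.full(n_genes, h)

    if geometry == "truncated":
        if not 0.0 < tau < 1.0:
            raise ValueError("truncation fraction tau must lie in (0, 1)")
        # programs spread a little beyond the axis so coverage never drops
        centers = np.linspace(-h / 2, 1.0 + h / 2, n_genes)
        t_b = np.sort(rng.uniform(0.0, tau, n_cells))
        centers_b = centers
        truth = {"tau": tau}
    elif geometry == "diverge_converge":
        d1, d2 = diverge_interval
        if not 0.0 < d1 < d2 < 1.0:
            raise ValueError("diverge interval must satisfy 0 < d1 < d2 < 1")
        t_b = np.sort(rng.uniform(0.0, 1.0, n_cells))
        # divergent pulses get their own width so their support fits the
        # interval exactly, whatever [d1, d2] is
        h_div = min(h, (d2 - d1) / 2.5)
        if h_div <= 0.01:
            raise ValueError("diverge interval too narrow; widen [d1, d2]")
        n_div = max(4, round(n_genes * (d2 - d1)))
        n_shared = n_genes - n_div
        # shared pulse centers keep out of the interval (support may leak in
        # by at most h/2 and does so identically on both sides)
        frac_lo = d1 / (d1 + 1.0 - d2)
        n_lo = min(n_shared - 1, max(1, round(n_shared * frac_lo)))
        lo_axis = np.linspace(-h / 2, d1 - h / 2, n_lo)
        hi_axis = np.linspace(d2 + h / 2, 1.0 + h / 2, n_shared - n_lo)
        shared_centers = np.concatenate([lo_axis, hi_axis])
        div_centers = np.linspace(d1 + h_div, d2 - h_div, n_div)
        centers = np.concatenate([shared_centers, div_centers])
        centers_b = centers.copy()
        halfwidths = np.concatenate(
            [np.full(n_shared, h), np.full(n_div, h_div)]
        )
        # each condition silences the other's half of the divergent genes
        own_a = np.arange(n_div) % 2 == 0
        amplitudes_div_a = amplitudes[n_shared:].copy()
        amplitudes_div_b = amplitudes[n_shared:].copy()
        amplitudes_div_a[~own_a] = 0.0
        amplitudes_div_b[own_a] = 0.0
        truth = {"d1": d1, "d2": d2, "n_shared_genes": int(n_shared)}
    else:  # negative_control
        # Two distinct regulatory networks: each drives its own half of the
        # gene panel while the other half sits at a common basal level, with
        # independent program order, kinetics (a mix of transient pulses and
        # switch-on sigmoids) and amplitudes per side. The dynamic genes of
        # each side tile its axis evenly, in random order, so coverage never
        # drops.
        half = n_genes // 2
        dynamic_a = np.arange(n_genes) < half
        basal = np.full(n_genes, 0.2)

        def _neg_side(t: np.ndarray, dynamic: np.ndarray) -> np.ndarray:
            nd = int(dynamic.sum())
            c = np.empty(n_genes)
            c[dynamic] = rng.permutation(np.linspace(-h / 2, 1.0 + h / 2, nd))
            c[~dynamic] = 0.5
            hw = rng.uniform(0.12, 0.3, n_genes)
            amp = amplitude * rng.uniform(0.7, 1.3, n_genes) * dynamic
            sigmoid = (rng.random(n_genes) < 0.5) & dynamic
            means = np.tile(basal[:, None], (1, len(t)))
            for k in np.nonzero(dynamic)[0]:
                if sigmoid[k]:
                    means[k] += amp[k] / (1.0 + np.exp(-(t - c[k]) / (hw[k] / 2)))
                else:
                    means[k] += amp[k] * _bump((t - c[k]) / hw[k])
            return means

        t_b = np.sort(rng.uniform(0.0, 1.0, n_cells))
        neg_means_a = _neg_side(t_a, dynamic_a)
        neg_means_b = _neg_side(t_b, ~dynamic_a)
        truth = {}

    if geometry == "diverge_converge":
        amp_a = np.concatenate([amplitudes[:n_shared], amplitudes_div_a])
        amp_b = np.concatenate([amplitudes[:n_shared], amplitudes_div_b])
        means_a = _program_means(t_a, centers, halfwidths, amp_a, baselines)
        means_b = _program_means(t_b, centers_b, halfwidths, amp_b, baselines)
    elif geometry == "negative_control":
        means_a = neg_means_a
        means_b = neg_means_b
    else:
        means_a = _program_means(t_a, centers, halfwidths, amplitudes, baselines)
        means_b = _program_means(t_b, centers_b, halfwidths, amplitudes, baselines)

    expr_a, pt_a = _observe(rng, t_a, means_a, nb_size, pt_jitter)
    expr_b, pt_b = _observe(rng, t_b, means_b, nb_size, pt_jitter)

    genes = [f"gene_{k:03d}" for k in range(n_genes)]
    traj_a = TrajectoryData(
        name="A",
        genes=genes,
        cells=[f"A_cell_{l:04d}" for l in range(n_cells)],
        expression=expr_a,
        pseudotime=pt_a,
    )
    traj_b = TrajectoryData(
        name="B",
        genes=list(genes),
        cells=[f"B_cell_{l:04d}" for l in range(n_cells)],
        expression=expr_b,
        pseudotime=pt_b,
    )
    return SyntheticPair(
        trajectory_a=traj_a,
        trajectory_b=traj_b,
        geometry=geometry,
        truth=truth,
        seed=seed,
        latent_a=t_a,
        latent_b=t_b,
    )


def simulate_null_pair(
    n_cells: int = 300,
    n_genes: int = 50,
    seed: int = 0,
    pulse_halfwidth: float = DEFAULT_PULSE_HALFWIDTH,
    amplitude: float = DEFAULT_AMPLITUDE,
    nb_size: float = DEFAULT_NB_SIZE,
    pt_jitter: float = DEFAULT_PT_JITTER,
) -> SyntheticPair:
    """Two independent draws from one generative model (a DE null).

    Both conditions follow the identical full-length program with their own
    cells, counts and pseudotime noise, so any differential expression call
    between them is a false positive.
    """
    rng = np.random.default_rng(seed)
    h = pulse_halfwidth
    t_a = np.sort(rng.uniform(0.0, 1.0, n_cells))
    t_b = np.sort(rng.uniform(0.0, 1.0, n_cells))
    baselines = rng.uniform(0.05, 0.3, n_genes)
    amplitudes = amplitude * rng.uniform(0.7, 1.3, n_genes)
    halfwidths = np.full(n_genes, h)
    centers = np.linspace(-h / 2, 1.0 + h / 2, n_genes)
    means_a = _program_means(t_a, centers, halfwidths, amplitudes, baselines)
    means_b = _program_means(t_b, centers, halfwidths, amplitudes, baselines)
    expr_a, pt_a = _observe(rng, t_a, means_a, nb_size, pt_jitter)
    expr_b, pt_b = _observe(rng, t_b, means_b, nb_size, pt_jitter)
    genes = [f"gene_{k:03d}" for k in range(n_genes)]
    return SyntheticPair(
        trajectory_a=TrajectoryData(
            "A", genes, [f"A_cell_{l:04d}" for l in range(n_cells)], expr_a, pt_a
        ),
        trajectory_b=TrajectoryData(
            "B", list(genes), [f"B_cell_{l:04d}" for l in range(n_cells)], expr_b, pt_b
        ),
        geometry="null",
        truth={},
        seed=seed,
        latent_a=t_a,
        latent_b=t_b,
    )


def score_alignment_against_truth(alignment, pair: SyntheticPair) -> dict:
    """Compare an alignment with the generative ground truth.

    For the truncated geometry, ``endpoint_error`` is the absolute
    difference, in fractions of A's axis, between the position of the A
    point matched to B's last kept point and the true truncation fraction
    ``tau``; ``b_terminates_early`` says whether B's kept path stops before
    A's final point. For diverge_converge, ``segment_recall`` is the
    fraction of ground-truth decisions the pruning got right: shared-segment
    matches kept plus divergent-interval matches pruned, over all
    unambiguous path matches. Interpolated-point positions stand in for
    latent time, which the jittered pseudotime tracks closely.
    """
    n, m = alignment.shape
    kept = alignment.kept_matches
    out: dict = {"geometry": pair.geometry}
    if pair.geometry == "truncated":
        tau = pair.truth["tau"]
        i_last, j_last = kept[-1]
        out["endpoint_error"] = abs(i_last / (n - 1) - tau)
        out["b_terminates_early"] = i_last < n - 1
    elif pair.geometry == "diverge_converge":
        d1, d2 = pair.truth["d1"], pair.truth["d2"]
        kept_set = set(kept)
        n_correct = n_total = 0
        for i, j in alignment.chosen.matches:
            f_a, f_b = i / (n - 1), j / (m - 1)
            inside_a = d1 <= f_a <= d2
            inside_b = d1 <= f_b <= d2
            if inside_a and inside_b:
                n_total += 1
                n_correct += (i, j) not in kept_set
            elif not inside_a and not inside_b:
                n_total += 1
                n_correct += (i, j) in kept_set
        out["segment_recall"] = n_correct / n_total if n_total else float("nan")
    return out


def write_pair(pair: SyntheticPair, outdir: str | Path) -> None:
    """Write the pair as CSV/TSV plus a truth JSON, for CLI use."""
    from trajalign.io import write_trajectory_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, traj in (("a", pair.trajectory_a), ("b", pair.trajectory_b)):
        write_trajectory_csv(
            traj,
            outdir / f"expression_{label}.csv",
            outdir / f"pseudotime_{label}.tsv",
        )
    meta = {"geometry": pair.geometry, "seed": pair.seed, **pair.truth}
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
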