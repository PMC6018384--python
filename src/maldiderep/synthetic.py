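"""Synthetic whole-cell MALDI-TOF collections and 16S-like sequence sets.

The spectrum generator emulates the hierarchical design of a recurrent-
isolate survey: cultures, each grown as independent biological replicates
(default 4), each measured as technical replicates (default 3). Every
culture owns a protein-like fingerprint of Gaussian peaks concentrated in
the 4-10 kDa range. Biological replication perturbs the fingerprint
itself (peak dropout, intensity rescaling); technical replication only
jitters masses (ppm-scale) and intensities, so with default settings
technical reproducibility exceeds biological reproducibility, as it does
for real measurements. Rendered traces add an exponentially decaying
chemical baseline and additive Gaussian noise, clipped at zero.

The sequence generator plants pairwise identities around the 98.65%
species cutoff by mutating a shared random ancestor at disjoint position
blocks, so identity between two sequences is exact:
100 * (L - k_i - k_j) / L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SampleRecord, Spectrum, SequenceRecord

__all__ = ["SynthConfig", "GroundTruth", "generate_collection", "generate_sequences"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic spectrum collection.

    Defaults mirror a typical survey: 4 biological x 3 technical
    replicates per culture, ~30 protein peaks per culture in 4-10 kDa,
    small technical variability (intensity CV 5%, 200 ppm mass jitter)
    and larger biological variability (intensity CV 25%, 5% peak
    dropout).
    """

    n_cultures: int = 10
    n_bio: int = 4
    n_tech: int = 3
    peaks_per_culture: int = 30
    mass_range: tuple[float, float] = (4000.0, 10000.0)
    mass_jitter_ppm: float = 200.0
    tech_intensity_cv: float = 0.05
    bio_intensity_cv: float = 0.25
    bio_peak_dropout: float = 0.05
    baseline_amplitude: float = 2.0
    noise_sd: float = 0.02
    peak_sigma_da: float = 5.0
    grid_low: float = 2000.0
    grid_high: float = 20000.0
    grid_step: float = 1.0
    n_phylotypes: int | None = None  # default: one phylotype per culture
    shared_peak_fraction: float = 0.7  # peaks shared within a phylotype
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cultures, self.n_bio, self.n_tech, self.peaks_per_culture) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.mass_range
        if not (2000.0 <= lo < hi <= 20000.0):
            raise ValueError("mass_range must lie within [2000, 20000]")
        if not 0.0 <= self.bio_peak_dropout <= 1.0:
            raise ValueError("bio_peak_dropout must be a probability")
        if self.n_phylotypes is not None and not (
            1 <= self.n_phylotypes <= self.n_cultures
        ):
            raise ValueError("n_phylotypes must be in [1, n_cultures]")


@dataclass
class GroundTruth:
    """What the generator planted: per-culture fingerprints and labels."""

    peak_masses: dict[str, np.ndarray]
    peak_heights: dict[str, np.ndarray]
    phylotype: dict[str, str]  # culture -> phylotype label
    config: SynthConfig


def _draw_fingerprint(
    rng: np.random.Generator, cfg: SynthConfig, n_peaks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Peak masses (min spacing 5 sigma) and lognormal base heights."""
    lo, hi = cfg.mass_range
    pad = 4 * cfg.peak_sigma_da
    spacing = 5 * cfg.peak_sigma_da
    masses: list[float] = []
    for _ in range(10000):
        if len(masses) == n_peaks:
            break
        m = rng.uniform(lo + pad, hi - pad)
        if all(abs(m - x) >= spacing for x in masses):
            masses.append(m)
    masses_arr = np.sort(np.array(masses))
    heights = rng.lognormal(mean=0.0, sigma=0.5, size=masses_arr.size) * 10.0
    return masses_arr, heights


def generate_collection(
    config: SynthConfig,
) -> tuple[list[Spectrum], list[SampleRecord], GroundTruth]:
    """Render the full culture x bio x tech spectrum collection.

    Deterministic given ``config.seed``. Returns raw (unpreprocessed)
    spectra on a uniform mass grid, matching sample records, and the
    planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = np.arange(config.grid_low, config.grid_high + config.grid_step / 2, config.grid_step)
    n_phylo = config.n_phylotypes or config.n_cultures
    phylo_of_culture = [i % n_phylo for i in range(config.n_cultures)]

    # phylotype-level shared fingerprints, plus culture-private peaks
    n_shared = (
        int(round(config.shared_peak_fraction * config.peaks_per_culture))
        if n_phylo < config.n_cultures
        else 0
    )
    shared: dict[int, tuple[np.ndarray, np.ndarray]] = {
        ph: _draw_fingerprint(rng, config, n_shared) if n_shared else (np.empty(0), np.empty(0))
        for ph in range(n_phylo)
    }

    peak_masses: dict[str, np.ndarray] = {}
    peak_heights: dict[str, np.ndarray] = {}
    phylotype: dict[str, str] = {}
    spectra: list[Spectrum] = []
    records: list[SampleRecord] = []

    decay = (config.grid_high - config.grid_low) / 4.0
    baseline = config.baseline_amplitude * np.exp(-(grid - config.grid_low) / decay)

    for c in range(config.n_cultures):
        culture_id = f"culture{c + 1:03d}"
        ph = phylo_of_culture[c]
        phylotype[culture_id] = f"phylotype{ph + 1:03d}"
        priv_m, priv_h = _draw_fingerprint(
            rng, config, config.peaks_per_culture - shared[ph][0].size
        )
        cm = np.concatenate([shared[ph][0], priv_m])
        ch = np.concatenate([shared[ph][1], priv_h])
        order = np.argsort(cm)
        cm, ch = cm[order], ch[order]
        peak_masses[culture_id] = cm
        peak_heights[culture_id] = ch
        for b in range(1, config.n_bio + 1):
            keep = rng.random(cm.size) >= config.bio_peak_dropout
            if not keep.any():
                keep[rng.integers(cm.size)] = True
            bio_scale = rng.lognormal(
                mean=-0.5 * np.log1p(config.bio_intensity_cv**2),
                sigma=np.sqrt(np.log1p(config.bio_intensity_cv**2)),
                size=cm.size,
            )
            bio_h = ch * bio_scale
            for t in range(1, config.n_tech + 1):
                sid = f"{culture_id}_b{b}_t{t}"
                jitter = rng.normal(0.0, config.mass_jitter_ppm * 1e-6 * cm[keep])
                tech_scale = rng.lognormal(
                    mean=-0.5 * np.log1p(config.tech_intensity_cv**2),
                    sigma=np.sqrt(np.log1p(config.tech_intensity_cv**2)),
                    size=int(keep.sum()),
                )
                pm = cm[keep] + jitter
                phh = bio_h[keep] * tech_scale
                trace = baseline.copy()
                for m0, h0 in zip(pm, phh):
                    lo_i = np.searchsorted(grid, m0 - 6 * config.peak_sigma_da)
                    hi_i = np.searchsorted(grid, m0 + 6 * config.peak_sigma_da)
                    seg = grid[lo_i:hi_i]
                    trace[lo_i:hi_i] += h0 * np.exp(
                        -0.5 * ((seg - m0) / config.peak_sigma_da) ** 2
                    )
                trace = np.clip(trace + rng.normal(0.0, config.noise_sd, grid.size), 0.0, None)
                spectra.append(Spectrum(sid, grid.copy(), trace))
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        culture_id=culture_id,
                        biological_replicate=b,
                        technical_replicate=t,
                    )
                )
    truth = GroundTruth(peak_masses, peak_heights, phylotype, config)
    return spectra, records, truth


_BASES = np.array(list("ACGT"))


def generate_sequences(
    n: int,
    length: int,
    planted_identity: np.ndarray | float,
    seed: int = 0,
    prefix: str = "seq",
    groups: list | None = None,
    ids: list[str] | None = None,
) -> list[SequenceRecord]:
    """Sequences with planted pairwise identities (substitutions only).

    ``planted_identity`` is either a scalar target identity (%) applied to
    every pair, or a full symmetric n x n matrix of targets in [70, 100].
    Sequences descend from a shared random root along a two-level star:
    each group (one per distinct ``groups`` label; all sequences form one
    group when omitted) mutates the root at a private block of ``c_g``
    positions, and each sequence mutates its group ancestor at a further
    private block of ``x_i`` positions. All blocks are disjoint and every
    position mutates to a fixed alternative base, so realised identities
    are exact: ``100 * (L - x_i - x_j) / L`` within a group and
    ``100 * (L - c_g - c_h - x_i - x_j) / L`` across groups. The loads are
    solved from the targets by least squares; targets no such additive
    configuration can realise within 0.3 identity points raise
    ``ValueError``.
    """
    if n < 1 or length < 10:
        raise ValueError("need n >= 1 and length >= 10")
    targets = np.asarray(planted_identity, dtype=float)
    if targets.ndim == 0:
        targets = np.full((n, n), float(targets))
        np.fill_diagonal(targets, 100.0)
    if targets.shape != (n, n):
        raise ValueError("planted_identity must be scalar or an n x n matrix")
    off = ~np.eye(n, dtype=bool)
    if n > 1 and (np.any(targets[off] < 70.0) or np.any(targets[off] > 100.0)):
        raise ValueError("pairwise identity targets must lie in [70, 100]")
    if groups is None:
        groups = [0] * n
    if len(groups) != n:
        raise ValueError("groups must have one label per sequence")
    glabels = sorted(set(groups), key=str)
    gidx = np.array([glabels.index(g) for g in groups])
    G = len(glabels)

    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=length)

    D = (100.0 - targets) / 100.0 * length  # target mutated-position distances
    # least squares for the n sequence loads and G group loads jointly:
    # d_ij = x_i + x_j (+ c_g(i) + c_g(j) across groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if pairs:
        A = np.zeros((len(pairs), n + G))
        d = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            A[r, i] = A[r, j] = 1.0
            if gidx[i] != gidx[j]:
                A[r, n + gidx[i]] += 1.0
                A[r, n + gidx[j]] += 1.0
            d[r] = D[i, j]
        sol, *_ = np.linalg.lstsq(A, d, rcond=None)
        x = np.maximum(np.round(sol[:n]), 0).astype(int)
        c = np.maximum(np.round(sol[n:]), 0).astype(int)
        achieved = x[:, None] + x[None, :] + np.where(
            gidx[:, None] != gidx[None, :], c[gidx][:, None] + c[gidx][None, :], 0
        )
        err = np.abs(achieved[off] - D[off]) / length * 100.0
        if np.any(err > 0.3):
            raise ValueError(
                "infeasible target combination: no additive mutation loads "
                f"match the requested identities (max deviation {err.max():.2f} points)"
            )
    else:
        x = np.zeros(n, dtype=int)
        c = np.zeros(G, dtype=int)
    if x.sum() + c.sum() > length:
        raise ValueError("targets require more mutated positions than the length allows")

    positions = rng.permutation(length)
    # deterministic substitution per position keeps shared mutations identical
    sub_shift = rng.integers(1, 4, size=length)
    base_idx = np.searchsorted(_BASES, ancestor)

    def mutate(seq: np.ndarray, block: np.ndarray) -> np.ndarray:
        out = seq.copy()
        out[block] = _BASES[(base_idx[block] + sub_shift[block]) % 4]
        return out

    cursor = 0
    group_anc = {}
    for g in range(G):
        group_anc[g] = mutate(ancestor, positions[cursor : cursor + c[g]])
        cursor += c[g]
    records = []
    for i in range(n):
        seq = mutate(group_anc[gidx[i]], positions[cursor : cursor + x[i]])
        cursor += x[i]
        sid = ids[i] if ids is not None else f"{prefix}{i + 1:03d}"
        records.append(SequenceRecord(sid, "".join(seq)))
    return records
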