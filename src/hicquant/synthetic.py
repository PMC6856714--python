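"""Paired-condition synthetic Hi-C maps with planted truth.

The generator emulates the statistical structure a cis contact-map analysis
assumes: power-law distance decay, multiplicative per-bin biases,
checkerboard compartments, contact domains, and point loops, sampled with
Poisson noise.  The pixel intensity on a chromosome is

    lambda(i, j) = Z * w_i w_j * (|i - j| + 1)^(-alpha)
                   * (1 + kappa * e_i e_j) * F(i, j)

where ``w`` are log-normal biases (log-sd beta), ``e`` is the planted +/-1
compartment vector, and ``F = D * L`` combines domain enrichment (``D``
multiplies by ``delta`` when both bins fall inside a domain) with loops
(``L = 1 + sum (phi - 1) exp(-((i-a)^2 + (j-b)^2) / (2 sigma^2))``).
Features are *marginal-preserving*: background pixels of feature-touching
bins are compensated down so each bin's total intensity is feature-neutral
(see ``build_intensity``).  ``Z`` scales the total intensity to the target
count ``N``; counts are Poisson.

Two conditions are modelled.  In the serum-like condition every feature is
at full strength.  In the 2i-like condition the excess enrichment
(``delta - 1``, ``phi - 1``) of *polycomb-class* features is multiplied by an
attenuation factor ``rho`` before sampling, while CTCF-class features are
untouched -- the in-silico analogue of polycomb redistribution upon DNA
hypomethylation with CTCF organisation retained.  rho = 1 leaves conditions
identical; rho = 0 removes polycomb features entirely.

Everything is deterministic given the spec's seed; planted truth (biases,
compartments, domains, loops, occupancy) is emitted alongside each dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrixio import GenomeBins, RawContactMatrix

__all__ = [
    "CTCF",
    "POLYCOMB",
    "DomainFeature",
    "LoopFeature",
    "SimulationSpec",
    "TruthTables",
    "SimulatedTracks",
    "build_intensity",
    "simulate_contact_map",
    "simulate_tracks",
    "default_spec",
    "graded_spec",
    "featureless_spec",
]

CTCF = "ctcf"
POLYCOMB = "polycomb"

SERUM = "serum"
TWOI = "2i"


@dataclass(frozen=True)
class DomainFeature:
    """Square on-diagonal contact enrichment over [start, end) (bp).

    ``focal`` features are marginal-compensated (their excess mass is taken
    out of the touched bins' background contacts); fields that tile the
    whole chromosome (TADs, graded compaction tiles) set ``focal=False`` and
    contribute their mass directly -- a quasi-uniform shift that cancels in
    observed/expected.
    """

    chrom: str
    start: int
    end: int
    enrichment: float  # delta >= 1
    klass: str = POLYCOMB
    focal: bool = True


@dataclass(frozen=True)
class LoopFeature:
    """Gaussian point enrichment between two anchors (bp positions)."""

    chrom: str
    pos1: int
    pos2: int
    amplitude: float  # phi >= 1
    sigma_bins: float = 1.0
    klass: str = CTCF


@dataclass
class SimulationSpec:
    chromsizes: dict[str, int]
    resolution: int = 5000
    total_count: float = 5e6
    decay_exponent: float = 1.0  # alpha
    bias_log_sd: float = 0.3  # beta
    compartment_amplitude: float = 0.3  # kappa
    compartment_block_bp: int = 800_000
    domains: list[DomainFeature] = field(default_factory=list)
    loops: list[LoopFeature] = field(default_factory=list)
    condition: str = SERUM
    attenuation: float = 0.0  # rho, applied to polycomb features in 2i only
    seed: int = 0
    sampling_seed: int | None = None  # per-replicate noise; None = use seed

    def validate(self) -> None:
        if self.resolution <= 0 or self.total_count <= 0:
            raise ValueError("resolution and total_count must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if self.bias_log_sd < 0:
            raise ValueError("bias log-sd beta must be >= 0")
        if not 0 <= self.compartment_amplitude < 1:
            raise ValueError("compartment amplitude kappa must be in [0, 1)")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation rho must be in [0, 1]")
        if self.condition not in (SERUM, TWOI):
            raise ValueError(f"condition must be {SERUM!r} or {TWOI!r}")
        for d in self.domains:
            if d.enrichment < 1 or not math.isfinite(d.enrichment):
                raise ValueError("domain enrichment delta must be finite and >= 1")
            if d.chrom not in self.chromsizes or not 0 <= d.start < d.end <= self.chromsizes[d.chrom]:
                raise ValueError(f"domain out of bounds: {d}")
        for lp in self.loops:
            if lp.amplitude < 1 or not math.isfinite(lp.amplitude):
                raise ValueError("loop amplitude phi must be finite and >= 1")
            if lp.sigma_bins <= 0:
                raise ValueError("loop sigma must be positive")
            if lp.chrom not in self.chromsizes:
                raise ValueError(f"loop on unknown chromosome: {lp}")

    def effective_enrichment(self, value: float, klass: str) -> float:
        """Feature strength after condition attenuation (serum-level otherwise)."""
        if self.condition == TWOI and klass == POLYCOMB:
            return 1.0 + self.attenuation * (value - 1.0)
        return float(value)

    def paired(self, condition: str) -> "SimulationSpec":
        """Same planted genome and seed, other condition switch."""
        return replace(self, condition=condition)

    def replicate(self, sampling_seed: int) -> "SimulationSpec":
        """Same planted genome, independent sampling noise (biases and
        Poisson draws) -- an in-silico library replicate."""
        return replace(self, sampling_seed=sampling_seed)

    @property
    def noise_seed(self) -> int:
        return self.seed if self.sampling_seed is None else self.sampling_seed


@dataclass
class TruthTables:
    """Planted ground truth, keyed by the generating seed."""

    seed: int
    condition: str
    compartments: dict[str, np.ndarray]  # +/-1 per bin
    biases: dict[str, np.ndarray]
    domains: pd.DataFrame  # chrom, start, end, enrichment, effective, klass
    loops: pd.DataFrame  # chrom, pos1, pos2, amplitude, effective, sigma_bins, klass
    occupancy: dict[str, np.ndarray]  # serum-level polycomb intensity per bin
    intensity_scale: float  # Z


@dataclass
class SimulatedTracks:
    occupancy: pd.DataFrame  # bedGraph-like, per bin
    gc: pd.DataFrame
    ring1b_peaks: pd.DataFrame  # BED-like
    ctcf_peaks: pd.DataFrame
    cgis: pd.DataFrame  # BED-like with name in {bound, unbound}
    loops: pd.DataFrame  # BEDPE-like with name = feature class


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(k) for k in key]])


def compartment_vector(spec: SimulationSpec, chrom: str) -> np.ndarray:
    """Deterministic +/-1 block vector (block length in bp, aligned to bins)."""
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    n = bins.n_bins(chrom)
    block_bins = max(1, spec.compartment_block_bp // spec.resolution)
    idx = np.arange(n) // block_bins
    return np.where(idx % 2 == 0, 1.0, -1.0)


def planted_biases(spec: SimulationSpec, chrom: str) -> np.ndarray:
    """Log-normal per-bin biases, shared between paired conditions."""
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    n = bins.n_bins(chrom)
    chrom_idx = list(spec.chromsizes).index(chrom)
    rng = _rng(spec.noise_seed, 0, chrom_idx)
    if spec.bias_log_sd == 0:
        return np.ones(n)
    w = rng.lognormal(mean=0.0, sigma=spec.bias_log_sd, size=n)
    return w / w.mean()


def feature_factor(spec: SimulationSpec, chrom: str, focal: bool = True) -> np.ndarray:
    """Dense symmetric feature factor (condition-attenuated).

    ``focal=True`` gives the compensated features (focal domains and all
    loops); ``focal=False`` the tiling background fields.  F is exactly the
    enrichment at feature pixels and 1 elsewhere; the sampled intensity
    carries F unchanged at feature pixels.
    """
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    n = bins.n_bins(chrom)
    res = spec.resolution
    F = np.ones((n, n))
    for d in spec.domains:
        if d.chrom != chrom or d.focal != focal:
            continue
        delta = spec.effective_enrichment(d.enrichment, d.klass)
        b0, b1 = d.start // res, -(-d.end // res)
        F[b0:b1, b0:b1] *= delta
    if not focal:
        return F
    for lp in spec.loops:
        if lp.chrom != chrom:
            continue
        phi = spec.effective_enrichment(lp.amplitude, lp.klass)
        if phi == 1.0:
            continue
        a, b = lp.pos1 // res, lp.pos2 // res
        half = int(math.ceil(4 * lp.sigma_bins))
        r0, r1 = max(0, a - half), min(n, a + half + 1)
        c0, c1 = max(0, b - half), min(n, b + half + 1)
        di = (np.arange(r0, r1) - a)[:, None]
        dj = (np.arange(c0, c1) - b)[None, :]
        bump = (phi - 1.0) * np.exp(-(di**2 + dj**2) / (2 * lp.sigma_bins**2))
        bump[bump < 1e-6] = 0.0
        F[r0:r1, c0:c1] *= 1.0 + bump
        F[c0:c1, r0:r1] *= 1.0 + bump.T  # keep the matrix symmetric
    return F


def build_intensity(spec: SimulationSpec, chrom: str) -> np.ndarray:
    """Unnormalized dense intensity matrix (full square; upper triangle used
    for sampling).  Exposed for closed-form checks.

    Features are marginal-preserving: a feature pixel carries the full
    enrichment ``F = D * L``, while the *background* pixels of every bin a
    feature touches are scaled by a compensation factor
    ``c_i = 1 - excess_i / background_i`` so the bin's total intensity stays
    what it would be without features.  Specific contacts form at the
    expense of a locus's diffuse contacts, not in addition to them: each
    sequenced fragment end ligates to exactly one partner, so true marginals
    carry no feature signal and balancing recovers exactly the planted
    biases.
    """
    spec.validate()
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    n = bins.n_bins(chrom)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    base = (sep + 1.0) ** (-spec.decay_exponent)
    del sep
    if spec.compartment_amplitude > 0:
        e = compartment_vector(spec, chrom)
        base *= 1.0 + spec.compartment_amplitude * e[:, None] * e[None, :]
    bg = feature_factor(spec, chrom, focal=False)
    if (bg != 1.0).any():
        base *= bg
    del bg
    F = feature_factor(spec, chrom, focal=True)
    is_feature = F != 1.0
    if is_feature.any():
        # redistribute, don't create: scale the background pixels of every
        # bin (symmetric Sinkhorn factors u) so each row's total intensity
        # equals its feature-free value exactly
        feat = np.where(is_feature, base * F, 0.0)
        featrow = feat.sum(axis=1)
        target = base.sum(axis=1)
        bg = np.where(is_feature, 0.0, base)
        deficit = target - featrow
        if np.any(deficit <= 0):
            raise ValueError(
                "feature mass exceeds a bin's total contact budget; "
                "reduce feature density or amplitudes"
            )
        u = np.ones(n)
        for _ in range(50):
            bgrow = u * (bg @ u)
            ratio = deficit / np.maximum(bgrow, 1e-300)
            if np.max(np.abs(ratio - 1.0)) < 1e-10:
                break
            u *= np.sqrt(ratio)
        lam = feat + bg * np.outer(u, u)
        del feat, bg
    else:
        lam = base
    del F, base
    w = planted_biases(spec, chrom)
    lam *= w[:, None] * w[None, :]
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite intensity; check spec parameters")
    return lam


def planted_occupancy(spec: SimulationSpec, chrom: str) -> np.ndarray:
    """Serum-level polycomb intensity per bin: excess domain enrichment plus
    Gaussian bumps at polycomb loop anchors.  This is what a serum ChIP
    track reads out, so it is not attenuated by the condition switch."""
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    n = bins.n_bins(chrom)
    res = spec.resolution
    occ = np.zeros(n)
    for d in spec.domains:
        if d.chrom != chrom or d.klass != POLYCOMB:
            continue
        occ[d.start // res : -(-d.end // res)] += d.enrichment - 1.0
    seen = set()
    for lp in spec.loops:
        if lp.chrom != chrom or lp.klass != POLYCOMB or lp.amplitude == 1.0:
            continue
        for pos in (lp.pos1, lp.pos2):
            a = pos // res
            if a in seen:
                continue
            seen.add(a)
            half = int(math.ceil(4 * lp.sigma_bins))
            r0, r1 = max(0, a - half), min(n, a + half + 1)
            occ[r0:r1] += (lp.amplitude - 1.0) * np.exp(
                -((np.arange(r0, r1) - a) ** 2) / (2 * lp.sigma_bins**2)
            )
    return occ


def simulate_contact_map(spec: SimulationSpec) -> tuple[RawContactMatrix, TruthTables]:
    """Sample a raw contact map and return it with its planted truth."""
    spec.validate()
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    lams = {c: build_intensity(spec, c) for c in bins.chroms}
    total = sum(float(np.triu(lam).sum()) for lam in lams.values())
    Z = spec.total_count / total
    mats = {}
    for k, chrom in enumerate(bins.chroms):
        rng = _rng(spec.noise_seed, 1, k)
        lam = np.triu(lams[chrom] * Z)
        counts = rng.poisson(lam)
        del lam
        i, j = np.nonzero(counts)
        mats[chrom] = sp.csr_matrix(
            (counts[i, j].astype(float), (i, j)), shape=counts.shape
        )
        del counts
        lams[chrom] = None
    raw = RawContactMatrix(bins, mats)
    truth = TruthTables(
        seed=spec.seed,
        condition=spec.condition,
        compartments={c: compartment_vector(spec, c) for c in bins.chroms},
        biases={c: planted_biases(spec, c) for c in bins.chroms},
        domains=pd.DataFrame(
            [
                {
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "enrichment": d.enrichment,
                    "effective": spec.effective_enrichment(d.enrichment, d.klass),
                    "klass": d.klass,
                }
                for d in spec.domains
            ]
        ),
        loops=pd.DataFrame(
            [
                {
                    "chrom": lp.chrom,
                    "pos1": lp.pos1,
                    "pos2": lp.pos2,
                    "amplitude": lp.amplitude,
                    "effective": spec.effective_enrichment(lp.amplitude, lp.klass),
                    "sigma_bins": lp.sigma_bins,
                    "klass": lp.klass,
                }
                for lp in spec.loops
            ]
        ),
        occupancy={c: planted_occupancy(spec, c) for c in bins.chroms},
        intensity_scale=Z,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# Tracks, peaks, CGIs and loop calls derived from the planted truth
# ---------------------------------------------------------------------------

def simulate_tracks(
    spec: SimulationSpec,
    truth: TruthTables,
    gamma: float = 10.0,
    noise_scale: float = 0.1,
    noise_log_sd: float = 0.5,
    gc_base: float = 0.42,
    gc_amplitude: float = 0.02,
    gc_noise_sd: float = 0.004,
) -> SimulatedTracks:
    """Emit occupancy/GC tracks, peak and CGI region sets, and loop calls.

    Occupancy per bin is ``gamma * intensity + noise`` with log-normal noise
    (scaled by ``noise_scale * gamma``); it emulates a serum ChIP read-density
    track over the planted polycomb intensity.  The GC track is an affine map
    of the compartment vector plus Gaussian noise, so eigenvector phasing is
    testable.  Peaks cover polycomb domains / CTCF anchors; CGIs are
    anchor-centred intervals labelled bound/unbound; loops are the planted
    anchor pairs as BEDPE.
    """
    if truth.seed != spec.seed:
        raise ValueError("truth tables were generated under a different seed")
    bins = GenomeBins(spec.chromsizes, spec.resolution)
    res = spec.resolution
    occ_rows, gc_rows = [], []
    for k, chrom in enumerate(bins.chroms):
        n = bins.n_bins(chrom)
        rng = _rng(spec.seed, 2, k)
        starts = np.arange(n, dtype=np.int64) * res
        ends = np.minimum(starts + res, spec.chromsizes[chrom])
        noise = noise_scale * gamma * rng.lognormal(0.0, noise_log_sd, size=n)
        occ = gamma * truth.occupancy[chrom] + (noise if noise_scale > 0 else 0.0)
        e = truth.compartments[chrom]
        gc = gc_base + gc_amplitude * e + rng.normal(0.0, gc_noise_sd, size=n)
        occ_rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": occ}))
        gc_rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": gc}))
    occupancy = pd.concat(occ_rows, ignore_index=True)
    gc_track = pd.concat(gc_rows, ignore_index=True)

    lp = truth.loops
    ctcf_bins = set()
    poly_anchor_pos: dict[str, set[int]] = {}
    if len(lp):
        for _, row in lp.iterrows():
            for pos in (row["pos1"], row["pos2"]):
                if row["klass"] == CTCF:
                    ctcf_bins.add((row["chrom"], int(pos) // res))
                else:
                    poly_anchor_pos.setdefault(row["chrom"], set()).add(int(pos))
    ctcf_peaks = pd.DataFrame(
        [
            {"chrom": c, "start": b * res, "end": min((b + 1) * res, spec.chromsizes[c]),
             "name": "ctcf_peak"}
            for c, b in sorted(ctcf_bins)
        ],
        columns=["chrom", "start", "end", "name"],
    )

    # RING1B peaks cover the polycomb occupancy domains and the bound-CGI
    # loop anchors (RING1B marks both in serum-grown cells)
    dom = truth.domains
    ring_rows = []
    if len(dom):
        for _, d in dom[dom["klass"] == POLYCOMB].iterrows():
            ring_rows.append({"chrom": d["chrom"], "start": int(d["start"]),
                              "end": int(d["end"]), "name": "ring1b_peak"})
    for chrom, positions in poly_anchor_pos.items():
        for pos in sorted(positions):
            b = pos // res
            ring_rows.append({"chrom": chrom, "start": b * res,
                              "end": min((b + 1) * res, spec.chromsizes[chrom]),
                              "name": "ring1b_peak"})
    ring1b = pd.DataFrame(ring_rows, columns=["chrom", "start", "end", "name"])

    # CGIs: bound = polycomb loop anchors; unbound = random bins kept clear of
    # every planted polycomb feature so they carry no contact enrichment.
    cgi_half = 1000
    cgi_rows = []
    for chrom in bins.chroms:
        positions = sorted(poly_anchor_pos.get(chrom, ()))
        for pos in positions:
            cgi_rows.append(
                {"chrom": chrom, "start": max(0, pos - cgi_half),
                 "end": min(spec.chromsizes[chrom], pos + cgi_half), "name": "bound"}
            )
        n = bins.n_bins(chrom)
        occ_chrom = truth.occupancy[chrom]
        clear = occ_chrom <= 0
        # stay >= 10 bins away from any planted polycomb signal or chrom edge
        kernel = 10
        blocked = ~clear
        pad = np.convolve(blocked.astype(int), np.ones(2 * kernel + 1, dtype=int), mode="same") > 0
        candidates = np.nonzero(~pad)[0]
        candidates = candidates[(candidates > kernel) & (candidates < n - kernel)]
        rng = _rng(spec.seed, 3, list(spec.chromsizes).index(chrom))
        n_unbound = len(positions)
        if n_unbound and len(candidates):
            chosen = rng.choice(candidates, size=min(n_unbound, len(candidates)), replace=False)
            for b in sorted(int(x) for x in chosen):
                center = b * res + res // 2
                cgi_rows.append(
                    {"chrom": chrom, "start": center - cgi_half, "end": center + cgi_half,
                     "name": "unbound"}
                )
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])

    loop_rows = []
    if len(lp):
        for _, row in lp.iterrows():
            b1, b2 = int(row["pos1"]) // res, int(row["pos2"]) // res
            loop_rows.append(
                {
                    "chrom1": row["chrom"], "start1": b1 * res, "end1": (b1 + 1) * res,
                    "chrom2": row["chrom"], "start2": b2 * res, "end2": (b2 + 1) * res,
                    "name": row["klass"],
                }
            )
    loops = pd.DataFrame(
        loop_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"],
    )
    return SimulatedTracks(occupancy, gc_track, ring1b, ctcf_peaks, cgis, loops)


# ---------------------------------------------------------------------------
# Spec factories: the study conditions at desk scale
# ---------------------------------------------------------------------------

def featureless_spec(
    seed: int,
    n_chroms: int = 1,
    chrom_length: int = 5_000_000,
    total_count: float = 2e6,
    bias_log_sd: float = 0.3,
    decay_exponent: float = 1.0,
    resolution: int = 5000,
) -> SimulationSpec:
    """Distance decay and biases only: no compartments, domains or loops."""
    chromsizes = {f"chr{k + 1}": chrom_length for k in range(n_chroms)}
    return SimulationSpec(
        chromsizes=chromsizes,
        resolution=resolution,
        total_count=total_count,
        decay_exponent=decay_exponent,
        bias_log_sd=bias_log_sd,
        compartment_amplitude=0.0,
        seed=seed,
    )


def default_spec(
    seed: int,
    condition: str = SERUM,
    attenuation: float = 0.0,
    n_chroms: int = 2,
    chrom_length: int = 10_000_000,
    resolution: int = 5000,
    total_count: float = 5e6,
    polycomb_phi: float | Sequence[float] = 3.0,
    ctcf_phi: float = 3.0,
    tad_enrichment: float = 1.5,
    domain_enrichment: float = 2.0,
    n_polycomb_domains: int = 10,
    n_cgi_anchors: int = 48,
    max_loop_span: int = 1_500_000,
    n_ctcf_sites: int = 60,
    n_ctcf_loops: int = 200,
) -> SimulationSpec:
    """Desk-scale default study conditions: 2 chromosomes x 10 Mb at 5 kb,
    5e6 cis counts.

    Planted structure per chromosome: tiling CTCF-class contact domains
    (TADs, 400 kb - 1 Mb, boundaries on the 25 kb grid); polycomb-class
    occupancy domains (20-100 kb, delta = 2); standalone RING1B-bound CGI
    anchors with loops between every anchor pair 260 kb - 1.5 Mb apart
    (polycomb CGIs interact combinatorially; phi cycles over
    ``polycomb_phi``); CTCF sites kept clear of polycomb features with loops
    between random site pairs 260 kb - 1.2 Mb apart.
    """
    chromsizes = {f"chr{k + 1}": chrom_length for k in range(n_chroms)}
    res = resolution
    domains: list[DomainFeature] = []
    loops: list[LoopFeature] = []
    phis = [polycomb_phi] if np.isscalar(polycomb_phi) else list(polycomb_phi)
    phi_cycle = 0
    for k, chrom in enumerate(chromsizes):
        rng = _rng(seed, 4, k)
        # tiling TADs on the 25 kb grid
        pos = 0
        while pos < chrom_length:
            length = int(rng.choice(np.arange(400_000, 1_000_001, 25_000)))
            end = min(pos + length, chrom_length)
            if chrom_length - end < 200_000:
                end = chrom_length
            domains.append(DomainFeature(chrom, pos, end, tad_enrichment, CTCF, focal=False))
            pos = end
        # polycomb occupancy domains, non-overlapping, clear of chromosome ends;
        # a domain bin's enriched mass must stay below its total contact
        # budget, which caps the domain width on short chromosomes
        max_dom = max(20_000, min(100_000, (chrom_length // 60) // 5000 * 5000))
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_polycomb_domains and attempts < 10_000:
            attempts += 1
            length = int(rng.choice(np.arange(20_000, max_dom + 1, 5_000)))
            start = int(rng.integers(60, (chrom_length - length) // res - 60)) * res
            if all(start >= e + 100_000 or start + length <= s - 100_000 for s, e in placed):
                placed.append((start, start + length))
        placed.sort()
        for s, e in placed:
            domains.append(DomainFeature(chrom, s, e, domain_enrichment, POLYCOMB))
        # standalone bound-CGI anchors, clear of domains and of each other;
        # loops between all anchor pairs within the separation band
        anchors: list[int] = []
        attempts = 0
        while len(anchors) < n_cgi_anchors and attempts < 20_000:
            attempts += 1
            pos_bp = int(rng.integers(60, chrom_length // res - 60)) * res + res // 2
            near_dom = any(s - 25_000 <= pos_bp < e + 25_000 for s, e in placed)
            if not near_dom and all(abs(pos_bp - a) >= 80_000 for a in anchors):
                anchors.append(pos_bp)
        anchors.sort()
        for ai in range(len(anchors)):
            for aj in range(ai + 1, len(anchors)):
                span = anchors[aj] - anchors[ai]
                if 260_000 <= span <= max_loop_span:
                    loops.append(
                        LoopFeature(
                            chrom, anchors[ai], anchors[aj],
                            float(phis[phi_cycle % len(phis)]), 1.0, POLYCOMB,
                        )
                    )
                    phi_cycle += 1
        # CTCF sites away from polycomb features, then random loop pairs
        sites: list[int] = []
        attempts = 0
        while len(sites) < n_ctcf_sites and attempts < 10_000:
            attempts += 1
            pos_bp = int(rng.integers(60, chrom_length // res - 60)) * res + res // 2
            near_poly = any(s - 15_000 <= pos_bp < e + 15_000 for s, e in placed)
            near_anchor = any(abs(pos_bp - a) < 25_000 for a in anchors)
            if not near_poly and not near_anchor and all(abs(pos_bp - s) >= 50_000 for s in sites):
                sites.append(pos_bp)
        sites.sort()
        pairs = [
            (sites[x], sites[y])
            for x in range(len(sites))
            for y in range(x + 1, len(sites))
            if 260_000 <= sites[y] - sites[x] <= 1_200_000
        ]
        if pairs:
            take = rng.choice(len(pairs), size=min(n_ctcf_loops, len(pairs)), replace=False)
            for t in sorted(int(x) for x in take):
                loops.append(LoopFeature(chrom, pairs[t][0], pairs[t][1], ctcf_phi, 1.0, CTCF))
    return SimulationSpec(
        chromsizes=chromsizes,
        resolution=res,
        total_count=total_count,
        decay_exponent=1.0,
        bias_log_sd=0.3,
        compartment_amplitude=0.3,
        compartment_block_bp=800_000,
        domains=domains,
        loops=loops,
        condition=condition,
        attenuation=attenuation,
        seed=seed,
    )


def graded_spec(
    seed: int,
    condition: str = SERUM,
    attenuation: float = 0.0,
    chrom_length: int = 5_000_000,
    resolution: int = 5000,
    total_count: float = 2e6,
    tile_bp: int = 25_000,
    max_excess: float = 1.0,
    smooth_bins: float = 6.0,
) -> SimulationSpec:
    """Occupancy-proportional local compaction: the chromosome is tiled with
    polycomb-class domains whose excess enrichment follows a smooth,
    rank-uniform occupancy field, so local interaction density is a graded,
    monotone function of occupancy across the whole genome."""
    chromsizes = {"chr1": chrom_length}
    bins = GenomeBins(chromsizes, resolution)
    n = bins.n_bins("chr1")
    rng = _rng(seed, 5, 0)
    g = rng.normal(0.0, 1.0, size=n)
    half = int(math.ceil(3 * smooth_bins))
    kern = np.exp(-(np.arange(-half, half + 1) ** 2) / (2 * smooth_bins**2))
    kern /= kern.sum()
    gs = np.convolve(g, kern, mode="same")
    # rank-uniform field in (0, 1]: every occupancy quantile is populated
    field = (np.argsort(np.argsort(gs)) + 1.0) / n
    tile_bins = tile_bp // resolution
    domains = []
    for t0 in range(0, n, tile_bins):
        t1 = min(t0 + tile_bins, n)
        delta = 1.0 + max_excess * float(field[t0:t1].mean())
        domains.append(
            DomainFeature("chr1", t0 * resolution, min(t1 * resolution, chrom_length),
                          delta, POLYCOMB, focal=False)
        )
    return SimulationSpec(
        chromsizes=chromsizes,
        resolution=resolution,
        total_count=total_count,
        decay_exponent=1.0,
        bias_log_sd=0.2,
        compartment_amplitude=0.0,
        domains=domains,
        loops=[],
        condition=condition,
        attenuation=attenuation,
        seed=seed,
    )
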