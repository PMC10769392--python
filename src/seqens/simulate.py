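"""Synthetic ground-truth model and seed-perturbed replicate ensembles.

The ground truth is a miniature sequence-to-activity model: per-bin
activity rates are a softplus link applied to a baseline plus the sum of
planted-PWM match contributions, each weighted by a signed per-track
effect weight and an exponential distance decay truncated at half the
receptive field. Replicate "models" share this ground truth but differ by
seeded perturbations, emulating ensemble members trained from different
random seeds:

* multiplicative lognormal noise on every motif effect weight
  (``exp(sigma * z)``), so replicates agree on strong effects and drift
  on weak ones;
* motif *recognition* noise: each member carries its own slightly
  perturbed copy of every PWM, with log-probability noise damped by
  (1 - p) so consensus recognition is stable while rare-base entries
  (partial and mutated matches) are member-dependent. This is what lets
  replicates disagree on the *direction* of small perturbation effects
  (a purely multiplicative weight perturbation is sign-preserving and
  could never produce the inconsistency gradients seen with real
  replicate ensembles);
* a low-amplitude smooth positional bias per member and track, and a
  small set of member-private low-weight "spurious motifs" with a short
  interaction range;
* shared counterparts of all components (common to every member),
  emulating the biases replicates inherit from their common training
  data; these produce consistently *incorrect* predictions.

At ``sigma = 0`` every member collapses exactly onto the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ASSAY_CLASSES, GenomicWindow, PWMMotif, TrackTable, VariantRecord
from . import consistency

__all__ = [
    "GroundTruthModel",
    "ReplicateMember",
    "ReplicateEnsemble",
    "make_motif_library",
    "make_ground_truth",
    "make_replicate_ensemble",
    "simulate_regulatory_genome",
    "ground_truth_predict",
    "simulate_track_counts",
    "simulate_eqtls",
    "simulate_population",
    "robust_window_contributions",
    "ensemble_robust_predict",
    "model_robust_predict",
]

_CODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_MIN_PROB = 1e-6  # floor under log-odds so zero-probability entries stay finite


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _logodds_lookup(matrix: np.ndarray) -> np.ndarray:
    """(L,5) log2-odds vs uniform background; column 4 (N) contributes 0."""
    w = np.log2(np.clip(matrix, _MIN_PROB, None) / 0.25)
    return np.concatenate([w, np.zeros((w.shape[0], 1))], axis=1)


def _revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    # reversing both axes maps A<->T and C<->G in A,C,G,T column order
    return matrix[::-1, ::-1]


def _decay_matrix(n_pos: int, motif_len: int, n_bins: int, bin_width: int,
                  decay_scale: float, receptive_field: int) -> np.ndarray:
    site_centers = np.arange(n_pos) + motif_len / 2.0
    bin_centers = (np.arange(n_bins) + 0.5) * bin_width
    d = np.abs(site_centers[:, None] - bin_centers[None, :])
    w = np.exp(-d / decay_scale)
    w[d > receptive_field / 2.0] = 0.0
    return w


def motif_score_threshold(motif: PWMMotif, fraction: float) -> float:
    """Site-score threshold: ``fraction`` of the motif's best possible log-odds."""
    best = float(np.log2(np.clip(motif.matrix.max(axis=1), _MIN_PROB, None) / 0.25).sum())
    return fraction * max(best, 0.0)


def batch_contributions(
    motifs: Sequence[PWMMotif],
    sequences: Sequence[str],
    bin_width: int,
    decay_scale: float,
    receptive_field: int,
    decay_scales: Optional[Sequence[float]] = None,
    match_threshold: float = 0.5,
    match_fractions: Optional[Sequence[float]] = None,
    saturations: Optional[Sequence[Optional[float]]] = None,
) -> np.ndarray:
    """Per-motif, per-bin match contributions for a batch of sequences.

    For every motif, both strands are scanned with log-odds scores vs a
    uniform background; only sites scoring above ``match_threshold`` of
    the motif's maximum achievable score contribute (by their excess
    score), each weighted by the truncated exponential decay from site
    center to bin center. The threshold keeps background matches sparse,
    as in standard motif scanning. Returns an (n_sequences, n_motifs,
    n_bins) array. Long batches are processed in chunks to bound the
    working-set size.
    """
    if not sequences:
        return np.zeros((0, len(motifs), 0))
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("all sequences in a batch must share one length")
    if length % bin_width != 0:
        raise ValueError(f"length {length} is not a multiple of bin width {bin_width}")
    n_bins = length // bin_width
    codes = np.empty((len(sequences), length), dtype=np.int8)
    for i, s in enumerate(sequences):
        codes[i] = encode_sequence(s)

    fractions = ([match_threshold] * len(motifs) if match_fractions is None
                 else [float(f) for f in match_fractions])
    # entries sharing one PWMMotif object (e.g. several score thresholds of
    # the same motif) reuse a single scan of the raw match scores
    groups: Dict[int, List[int]] = {}
    for m, motif in enumerate(motifs):
        groups.setdefault(id(motif), []).append(m)

    out = np.zeros((len(sequences), len(motifs), n_bins))
    decay_cache: Dict[tuple, np.ndarray] = {}
    chunk = max(1, int(2**24 // max(length, 1)))  # ~128 MB of float64 scores
    for lo in range(0, len(sequences), chunk):
        sub = codes[lo:lo + chunk]
        for entries in groups.values():
            motif = motifs[entries[0]]
            l = len(motif)
            if l > length:
                raise ValueError(f"motif {motif.motif_id} longer than the window")
            n_pos = length - l + 1
            for mat in (motif.matrix, _revcomp_matrix(motif.matrix)):
                lut = _logodds_lookup(mat)
                raw = np.zeros((sub.shape[0], n_pos))
                for j in range(l):
                    raw += lut[j][sub[:, j:j + n_pos]]
                for m in entries:
                    scale = decay_scale if decay_scales is None else float(decay_scales[m])
                    if (l, scale) not in decay_cache:
                        decay_cache[(l, scale)] = _decay_matrix(
                            n_pos, l, n_bins, bin_width, scale, receptive_field)
                    tau = motif_score_threshold(motif, fractions[m])
                    excess = np.maximum(raw - tau, 0.0)
                    cap = None if saturations is None else saturations[m]
                    if cap is not None:
                        excess = cap * np.tanh(excess / cap)
                    out[lo:lo + chunk, m, :] += excess @ decay_cache[(l, scale)]
    return out


def _softplus(x: np.ndarray, sharpness: float) -> np.ndarray:
    return np.logaddexp(0.0, sharpness * x) / sharpness


def _softplus_inv(y: float, sharpness: float) -> float:
    return math.log(math.expm1(sharpness * y)) / sharpness


@dataclass
class GroundTruthModel:
    """The oracle sequence-to-activity model f*."""

    motifs: List[PWMMotif]
    weights: np.ndarray  # (n_tracks, n_motifs), signed effect weights
    track_ids: List[str]
    assay_classes: List[str]
    baseline_rate: float = 2.0
    decay_scale: float = 500.0
    receptive_field: int = 2048
    bin_width: int = 128
    sharpness: float = 1.0
    match_threshold: float = 0.5
    site_saturation: Optional[float] = None

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape != (len(self.track_ids), len(self.motifs)):
            raise ValueError("weights must be (n_tracks, n_motifs)")
        if self.baseline_rate <= 0 or self.decay_scale <= 0:
            raise ValueError("baseline_rate and decay_scale must be positive")

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    @property
    def score0(self) -> float:
        return _softplus_inv(self.baseline_rate, self.sharpness)

    def track_index(self, track: Optional[str]) -> int:
        if track is None:
            return 0
        try:
            return self.track_ids.index(track)
        except ValueError:
            raise KeyError(f"unknown track {track!r}") from None

    def contributions(self, sequences: Sequence[str]) -> np.ndarray:
        if sequences and self.receptive_field > len(sequences[0]):
            raise ValueError("receptive field exceeds the window length")
        return batch_contributions(self.motifs, sequences, self.bin_width,
                                   self.decay_scale, self.receptive_field,
                                   match_threshold=self.match_threshold,
                                   saturations=[self.site_saturation] * len(self.motifs))

    def predict_sequences(self, sequences: Sequence[str], track: Optional[str] = None) -> np.ndarray:
        c = self.contributions(sequences)
        t = self.track_index(track)
        return _softplus(self.score0 + np.einsum("nmb,m->nb", c, self.weights[t]),
                         self.sharpness)

    def predict(self, window: GenomicWindow, track: Optional[str] = None) -> np.ndarray:
        return self.predict_sequences([window.sequence], track)[0]

    def predict_tracks(self, window: GenomicWindow) -> np.ndarray:
        """(n_tracks, n_bins) rates for one window."""
        c = self.contributions([window.sequence])[0]
        return _softplus(self.score0 + self.weights @ c, self.sharpness)


def ground_truth_predict(model: GroundTruthModel, window: GenomicWindow,
                         track: Optional[str] = None) -> TrackTable:
    """Oracle rates for one window as a TrackTable (strictly positive)."""
    t = model.track_index(track)
    return TrackTable(
        track_id=model.track_ids[t],
        assay_class=model.assay_classes[t],
        values=model.predict(window, track=track),
        bin_width=model.bin_width,
    )


@dataclass
class ReplicateMember:
    """One seed-perturbed replicate of the ground truth (a pure function)."""

    model: GroundTruthModel
    seed: int
    sigma: float
    scan_motifs: List[PWMMotif]
    eff_weights: np.ndarray          # (n_tracks, n_scan_motifs)
    bias_amp: np.ndarray             # (n_tracks, K)
    bias_phase: np.ndarray           # (n_tracks, K)
    scan_decay_scales: Optional[List[float]] = None
    scan_match_fractions: Optional[List[float]] = None
    scan_saturations: Optional[List[Optional[float]]] = None
    motif_block: Optional[slice] = None  # this member's motif-library slice

    @property
    def motif_weights(self) -> np.ndarray:
        """(n_tracks, n_motifs) effective weights on the member's motif library."""
        if self.motif_block is None:
            return self.eff_weights
        return self.eff_weights[:, self.motif_block]
    _bias_cache: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def bias(self, n_bins: int) -> np.ndarray:
        """(n_tracks, n_bins) smooth positional bias added pre-link."""
        if n_bins not in self._bias_cache:
            n_terms = self.bias_amp.shape[1]
            k = np.arange(n_terms) % 3 + 1  # cosine harmonics 1..3 per component
            phase = 2 * np.pi * k[None, :, None] * (np.arange(n_bins)[None, None, :] + 0.5) / n_bins
            self._bias_cache[n_bins] = np.sum(
                self.bias_amp[:, :, None] * np.cos(phase + self.bias_phase[:, :, None]),
                axis=1,
            )
        return self._bias_cache[n_bins]

    def _rates(self, contrib: np.ndarray, t: int) -> np.ndarray:
        n_bins = contrib.shape[-1]
        z = self.model.score0 + np.einsum("...mb,m->...b", contrib, self.eff_weights[t])
        return _softplus(z + self.bias(n_bins)[t], self.model.sharpness)

    def predict_sequences(self, sequences: Sequence[str], track: Optional[str] = None) -> np.ndarray:
        c = batch_contributions(self.scan_motifs, sequences, self.model.bin_width,
                                self.model.decay_scale, self.model.receptive_field,
                                decay_scales=self.scan_decay_scales,
                                match_threshold=self.model.match_threshold,
                                match_fractions=self.scan_match_fractions,
                                saturations=self.scan_saturations)
        return self._rates(c, self.model.track_index(track))

    def predict(self, window: GenomicWindow, track: Optional[str] = None) -> np.ndarray:
        return self.predict_sequences([window.sequence], track)[0]


@dataclass
class ReplicateEnsemble:
    """M replicate predictors sharing one input/output contract."""

    model: GroundTruthModel
    members: List[ReplicateMember]
    sigma: float
    seeds: List[int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("consistency analysis requires M >= 2 replicates")

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def scan_motifs(self) -> List[PWMMotif]:
        return self.members[0].scan_motifs

    @property
    def scan_decay_scales(self) -> Optional[List[float]]:
        return self.members[0].scan_decay_scales

    @property
    def scan_match_fractions(self) -> Optional[List[float]]:
        return self.members[0].scan_match_fractions

    @property
    def scan_saturations(self) -> Optional[List[Optional[float]]]:
        return self.members[0].scan_saturations


def _random_pwm(rng: np.random.Generator, length: int, motif_id: str,
                min_info: float = 0.6, max_info: float = 0.95,
                pseudocount: float = 0.02) -> PWMMotif:
    mat = np.empty((length, 4))
    for i in range(length):
        cons = rng.integers(4)
        p = rng.uniform(min_info, max_info)
        rest = rng.dirichlet(np.ones(3)) * (1 - p)
        row = np.insert(rest, cons, p)
        # pseudocount floor, as applied to empirical motif count matrices:
        # a single disruptive substitution weakens a site without erasing it
        row = row * (1 - 4 * pseudocount) + pseudocount
        mat[i] = row / row.sum()
    return PWMMotif(motif_id=motif_id, matrix=mat)


def make_motif_library(n_motifs: int = 8, motif_length: int = 8,
                       seed: int = 0) -> List[PWMMotif]:
    rng = np.random.default_rng(seed)
    return [_random_pwm(rng, motif_length, f"MOTIF{i:02d}") for i in range(n_motifs)]


def make_ground_truth(
    n_tracks: int = 8,
    n_motifs: int = 8,
    motif_length: int = 8,
    seed: int = 0,
    activator_fraction: float = 0.7,
    pseudocount: float = 0.06,
    match_threshold: float = 0.25,
    site_saturation: Optional[float] = 0.8,
    baseline_rate: float = 2.0,
    decay_scale: float = 500.0,
    receptive_field: int = 2048,
    bin_width: int = 128,
) -> GroundTruthModel:
    """Build a ground-truth model with a synthetic motif library.

    Motif effect weights are signed (activators/repressors) with
    lognormal per-track modulation so tracks respond to the same motifs
    with different strengths.
    """
    rng = np.random.default_rng(seed)
    motifs = [_random_pwm(rng, motif_length, f"MOTIF{i:02d}", pseudocount=pseudocount)
              for i in range(n_motifs)]
    signs = np.where(rng.random(n_motifs) < activator_fraction, 1.0, -1.0)
    base = signs * (0.08 + 0.22 * np.abs(rng.standard_normal(n_motifs)))
    track_mod = np.exp(0.3 * rng.standard_normal((n_tracks, n_motifs)))
    weights = base[None, :] * track_mod
    assay = [ASSAY_CLASSES[i % len(ASSAY_CLASSES)] for i in range(n_tracks)]
    track_ids = [f"{assay[i]}_{i}" for i in range(n_tracks)]
    return GroundTruthModel(
        motifs=motifs, weights=weights, track_ids=track_ids, assay_classes=assay,
        baseline_rate=baseline_rate, decay_scale=decay_scale,
        receptive_field=receptive_field, bin_width=bin_width,
        match_threshold=match_threshold, site_saturation=site_saturation,
    )


def _band_field_scales(model: GroundTruthModel, noise_decay: float,
                       band_fractions: Tuple[float, float] = (0.5, 0.75)) -> np.ndarray:
    """1/std of each motif's damaged-site ("bump") background field.

    Estimated once per model on seeded probe sequences and cached, so the
    damaged-site weights are in units of per-bin background-field std.
    """
    key = (noise_decay, tuple(band_fractions))
    cache = getattr(model, "_band_scale_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    rng = np.random.default_rng(424242)
    probes = ["".join(rng.choice(list("ACGT"), size=2048)) for _ in range(6)]
    mt = model.match_threshold
    motifs3 = list(model.motifs) * 3
    lo_f, mid_f = band_fractions
    fractions = ([lo_f * mt] * len(model.motifs) + [mid_f * mt] * len(model.motifs) +
                 [mt] * len(model.motifs))
    c = batch_contributions(motifs3, probes, model.bin_width, noise_decay,
                            model.receptive_field,
                            decay_scales=[noise_decay] * len(motifs3),
                            match_fractions=fractions)
    n = len(model.motifs)
    bump = c[:, :n, :] - 2.0 * c[:, n:2 * n, :] + c[:, 2 * n:, :]
    std = bump.std(axis=(0, 2))
    scales = 1.0 / np.maximum(std, 0.1)
    model._band_scale_cache = (key, scales)
    return scales


def make_replicate_ensemble(
    model: GroundTruthModel,
    m: int = 5,
    sigma: float = 0.5,
    seeds: Optional[Sequence[int]] = None,
    weight_noise: float = 0.35,
    shared_weight_noise: float = 0.25,
    pwm_noise: float = 0.6,
    shared_pwm_noise: float = 0.8,
    damaged_weight: float = 0.45,
    shared_damaged_weight: float = 0.35,
    rare_entry_noise: float = 0.0,
    noise_decay: Optional[float] = None,
    n_spurious: int = 2,
    spurious_weight: float = 0.15,
    n_shared_spurious: int = 2,
    shared_spurious_weight: float = 0.10,
    spurious_length: int = 6,
    spurious_decay: float = 64.0,
    band_fractions: Tuple[float, float] = (0.5, 0.75),
    bias_amplitude: float = 0.1,
    shared_bias_amplitude: float = 0.05,
    shared_seed: Optional[int] = None,
) -> ReplicateEnsemble:
    """M seed-perturbed replicates of ``model`` with disagreement scale sigma.

    Each member's perturbation has a member-specific part (weight
    multipliers exp(sigma*weight_noise*z_i), perturbed motif matrices
    controlled by ``pwm_noise``, a private positional bias, ``n_spurious``
    private spurious motifs) and a part shared by the whole ensemble
    (``shared_*`` counterparts), emulating replicates trained from the
    same finite dataset: the shared part shifts all replicates together
    (producing consistently *incorrect* predictions), the member part
    makes them disagree. All random draws are taken regardless of sigma
    and scaled afterwards, so the same seeds give comparable members
    across a sigma grid; sigma=0 reproduces the ground truth exactly.
    """
    if m < 2:
        raise ValueError("consistency analysis requires M >= 2 replicates")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if seeds is None:
        seeds = list(range(m))
    seeds = [int(s) for s in seeds]
    if len(seeds) != m:
        raise ValueError("need one seed per member")
    if len(set(seeds)) != m:
        raise ValueError("duplicate member seeds")
    if shared_seed is None:
        import zlib

        shared_seed = zlib.crc32(",".join(map(str, seeds)).encode()) & 0x7FFFFFFF

    n_tracks, n_shared = model.weights.shape
    k = 3  # cosine harmonics in the positional bias

    def _field_scale(motif: PWMMotif, probe_rng: np.random.Generator) -> float:
        # std of the motif's background contribution field on probe sequences,
        # so every private feature injects comparable per-bin noise
        probes = ["".join(probe_rng.choice(list("ACGT"), size=1024))
                  for _ in range(6)]
        c = batch_contributions([motif], probes, model.bin_width,
                                spurious_decay, model.receptive_field,
                                match_threshold=model.match_threshold)
        std = float(c.std())
        return 1.0 / max(std, 0.1)

    srng = np.random.default_rng(shared_seed)
    z_sh = srng.standard_normal((n_tracks, n_shared))
    spur_sh = [_random_pwm(srng, spurious_length, f"SPURSH_{j}", 0.55, 0.9)
               for j in range(n_shared_spurious)]
    scale_sh = np.array([_field_scale(mo, np.random.default_rng(shared_seed + 7 + j))
                         for j, mo in enumerate(spur_sh)])
    g_sh = srng.standard_normal((n_tracks, n_shared_spurious)) * scale_sh[None, :]
    amp_sh = srng.standard_normal((n_tracks, k)) / np.arange(1, k + 1)
    phase_sh = srng.uniform(0, 2 * np.pi, size=(n_tracks, k))

    e_sh = [srng.standard_normal(mo.matrix.shape) for mo in model.motifs]

    draws = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_tracks, n_shared))
        e = [rng.standard_normal(model.motifs[j].matrix.shape) for j in range(n_shared)]
        spur = [_random_pwm(rng, spurious_length, f"SPUR{seed}_{j}", 0.55, 0.9)
                for j in range(n_spurious)]
        scale = np.array([_field_scale(mo, np.random.default_rng(seed * 13 + 7 + j))
                          for j, mo in enumerate(spur)])
        g = rng.standard_normal((n_tracks, n_spurious)) * scale[None, :]
        amp = rng.standard_normal((n_tracks, k)) / np.arange(1, k + 1)
        phase = rng.uniform(0, 2 * np.pi, size=(n_tracks, k))
        draws.append((z, e, spur, g, amp, phase))

    def _perturb_pwm(motif: PWMMotif, noise: np.ndarray, tag: str) -> PWMMotif:
        # replicates agree on consensus recognition but drift on the rare
        # bases: log-probability noise damped by (1 - p) leaves high-prob
        # entries nearly fixed and low-prob entries (partial and mutated
        # matches) member-dependent; rare_entry_noise optionally adds
        # heavy-tailed noise to near-zero entries
        damping = (1.0 - motif.matrix) * np.where(motif.matrix < 0.06,
                                                  1.0 + rare_entry_noise, 1.0)
        mat = motif.matrix * np.exp(noise * damping)
        mat = mat / mat.sum(axis=1, keepdims=True)
        return PWMMotif(motif_id=f"{motif.motif_id}~{tag}", matrix=mat)

    eta_sh = srng.standard_normal(n_shared)
    etas = [np.random.default_rng(seed * 17 + 3).standard_normal(n_shared)
            for seed in seeds]
    if noise_decay is None:
        noise_decay = 1.6 * model.decay_scale
    band_scales = _band_field_scales(model, noise_decay, band_fractions)

    perturbed = sigma > 0
    mt = model.match_threshold
    sat = model.site_saturation
    scan_motifs: List[PWMMotif] = []
    decay_scales: List[float] = []
    fractions: List[float] = []
    saturations: List[Optional[float]] = []
    blocks: List[slice] = []
    band_blocks: List[Tuple[slice, slice, slice]] = []
    spur_starts: List[int] = []
    sh_block = 0
    if not perturbed:
        # sigma = 0: every member IS the ground truth; scan its motifs once
        scan_motifs = list(model.motifs)
        decay_scales = [model.decay_scale] * n_shared
        fractions = [mt] * n_shared
        saturations = [sat] * n_shared
        blocks = [slice(0, n_shared)] * m
    else:
        for i, (seed, (z, e, spur, g, amp, phase)) in enumerate(zip(seeds, draws)):
            start = len(scan_motifs)
            # each member recognizes slightly different versions of the motifs;
            # the same perturbed matrix is scanned at several score thresholds
            # so a triangular "damaged site" band (zero for intact sites) can
            # be weighted separately from intact sites
            member_motifs = []
            for j, motif in enumerate(model.motifs):
                noise = sigma * (shared_pwm_noise * e_sh[j] + pwm_noise * e[j])
                member_motifs.append(_perturb_pwm(motif, noise, f"rep{seed}"))
            scan_motifs.extend(member_motifs)          # intact: relu(S - tau)
            scan_motifs.extend(member_motifs)          # band lo
            scan_motifs.extend(member_motifs)          # band mid
            scan_motifs.extend(member_motifs)          # band hi: relu(S - tau)
            lo_f, mid_f = band_fractions
            decay_scales += [model.decay_scale] * n_shared + [noise_decay] * (3 * n_shared)
            fractions += ([mt] * n_shared + [lo_f * mt] * n_shared +
                          [mid_f * mt] * n_shared + [mt] * n_shared)
            saturations += [sat] * n_shared + [None] * (3 * n_shared)
            blocks.append(slice(start, start + n_shared))
            band_blocks.append((
                slice(start + n_shared, start + 2 * n_shared),
                slice(start + 2 * n_shared, start + 3 * n_shared),
                slice(start + 3 * n_shared, start + 4 * n_shared),
            ))
        sh_block = len(scan_motifs)
        scan_motifs.extend(spur_sh)
        decay_scales += [spurious_decay] * len(spur_sh)
        fractions += [mt] * len(spur_sh)
        saturations += [None] * len(spur_sh)
        for seed, (z, e, spur, g, amp, phase) in zip(seeds, draws):
            spur_starts.append(len(scan_motifs))
            scan_motifs.extend(spur)
            # member-private features act locally: a short decay keeps the
            # diffuse background field small relative to its local deltas
            decay_scales += [spurious_decay] * len(spur)
            fractions += [mt] * len(spur)
            saturations += [None] * len(spur)

    members = []
    for i, (seed, (z, e, spur, g, amp, phase)) in enumerate(zip(seeds, draws)):
        eff = np.zeros((n_tracks, len(scan_motifs)))
        w_i = model.weights * np.exp(
            sigma * (shared_weight_noise * z_sh + weight_noise * z))
        eff[:, blocks[i]] = w_i
        if perturbed:
            # member-specific signed response to damaged (band-scoring) sites:
            # bump(S) = relu(S-lo) - 2 relu(S-mid) + relu(S-hi) is zero for
            # intact sites, so replicates disagree on whether a broken motif
            # retains function; normalized to unit background-field std
            lo_b, mid_b, hi_b = band_blocks[i]
            beta = sigma * (damaged_weight * etas[i] +
                            shared_damaged_weight * eta_sh) * band_scales
            beta = np.broadcast_to(beta, (n_tracks, n_shared))
            eff[:, lo_b] = beta
            eff[:, mid_b] = -2.0 * beta
            eff[:, hi_b] = beta
            eff[:, sh_block:sh_block + len(spur_sh)] = \
                sigma * shared_spurious_weight * g_sh
            eff[:, spur_starts[i]:spur_starts[i] + len(spur)] = \
                sigma * spurious_weight * g
        members.append(ReplicateMember(
            model=model, seed=seed, sigma=sigma, scan_motifs=scan_motifs,
            eff_weights=eff,
            bias_amp=np.concatenate([sigma * shared_bias_amplitude * amp_sh,
                                     sigma * bias_amplitude * amp], axis=1),
            bias_phase=np.concatenate([phase_sh, phase], axis=1),
            scan_decay_scales=list(decay_scales),
            scan_match_fractions=list(fractions),
            scan_saturations=list(saturations),
            motif_block=blocks[i],
        ))
    return ReplicateEnsemble(model=model, members=members, sigma=sigma, seeds=list(seeds))


# ---------------------------------------------------------------------------
# fast augmented (shift x strand) prediction paths
# ---------------------------------------------------------------------------

_RC_SLOTS = np.array([False, True, False, True, False, True])


def robust_window_contributions(motifs: Sequence[PWMMotif], windows: Sequence[GenomicWindow],
                                bin_width: int, decay_scale: float,
                                receptive_field: int,
                                decay_scales: Optional[Sequence[float]] = None,
                                match_threshold: float = 0.5,
                                match_fractions: Optional[Sequence[float]] = None,
                                saturations: Optional[Sequence[Optional[float]]] = None) -> np.ndarray:
    """Contributions for all 6 augmentations of each window.

    Returns (n_windows, 6, n_motifs, n_bins); slot order matches
    :func:`seqens.consistency.augmented_windows`. Reusable across ensemble
    members and across a sigma grid built from the same member seeds.
    """
    seqs: List[str] = []
    for w in windows:
        for aug, _ in consistency.augmented_windows(w):
            seqs.append(aug.sequence)
    c = batch_contributions(motifs, seqs, bin_width, decay_scale, receptive_field,
                            decay_scales=decay_scales, match_threshold=match_threshold,
                            match_fractions=match_fractions, saturations=saturations)
    n_bins = c.shape[-1]
    return c.reshape(len(windows), 6, len(motifs), n_bins)


def ensemble_robust_predict(
    ensemble: ReplicateEnsemble,
    windows: Sequence[GenomicWindow],
    track: Optional[str] = None,
    contributions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(M, n_windows, n_bins) augmentation-averaged rates for every member.

    Equivalent to looping :func:`seqens.consistency.robust_predict` over
    members, but scans each augmented sequence once and reuses the match
    contributions for all members. Pass ``contributions`` (from
    :func:`robust_window_contributions` over ``ensemble.scan_motifs``) to
    reuse scans across calls.
    """
    model = ensemble.model
    if contributions is None:
        contributions = robust_window_contributions(
            ensemble.scan_motifs, windows, model.bin_width,
            model.decay_scale, model.receptive_field,
            decay_scales=ensemble.scan_decay_scales,
            match_threshold=model.match_threshold,
            match_fractions=ensemble.scan_match_fractions,
            saturations=ensemble.scan_saturations)
    t = model.track_index(track)
    n_win, _, n_scan, n_bins = contributions.shape
    if n_scan != len(ensemble.scan_motifs):
        raise ValueError("contributions were computed for a different motif set")
    out = np.empty((ensemble.m, n_win, n_bins))
    for i, mem in enumerate(ensemble.members):
        rates = mem._rates(contributions, t)  # (n_win, 6, n_bins)
        rates[:, _RC_SLOTS, :] = rates[:, _RC_SLOTS, ::-1]
        out[i] = rates.mean(axis=1)
    return out


def model_robust_predict(model: GroundTruthModel, windows: Sequence[GenomicWindow],
                         track: Optional[str] = None,
                         contributions: Optional[np.ndarray] = None) -> np.ndarray:
    """(n_windows, n_bins) augmentation-averaged ground-truth rates (batched)."""
    if contributions is None:
        contributions = robust_window_contributions(
            model.motifs, windows, model.bin_width, model.decay_scale,
            model.receptive_field, match_threshold=model.match_threshold,
            saturations=[model.site_saturation] * len(model.motifs))
    t = model.track_index(track)
    z = model.score0 + np.einsum("nsmb,m->nsb", contributions, model.weights[t])
    rates = _softplus(z, model.sharpness)
    rates[:, _RC_SLOTS, :] = rates[:, _RC_SLOTS, ::-1]
    return rates.mean(axis=1)


# ---------------------------------------------------------------------------
# dataset simulators
# ---------------------------------------------------------------------------

_BG_ORDER = "ACGT"


def simulate_regulatory_genome(
    n_windows: int,
    length: int,
    gc: float = 0.41,
    motif_density: float = 0.5,
    seed: int = 0,
    motif_library: Optional[Sequence[PWMMotif]] = None,
    bin_width: int = 128,
    chrom_prefix: str = "synt",
) -> Tuple[List[GenomicWindow], pd.DataFrame]:
    """Background windows with planted PWM instances around a central TSS.

    Bases are i.i.d. with the requested GC fraction; planted instances are
    sampled from each motif's PWM (Poisson(motif_density per kb) sites per
    window, uniform positions/strands) and recorded in the returned site
    table. The TSS anchor sits at the window center (a bin junction).
    """
    if not (0 < gc < 1):
        raise ValueError("gc must lie strictly between 0 and 1")
    if length % bin_width != 0:
        raise ValueError("window length must be a multiple of the bin width")
    if motif_library is None:
        motif_library = make_motif_library(seed=seed)
    for motif in motif_library:
        if len(motif) > length:
            raise ValueError(f"motif {motif.motif_id} longer than the window")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    windows: List[GenomicWindow] = []
    rows = []
    for i in range(n_windows):
        seq = rng.choice(list(_BG_ORDER), size=length, p=probs)
        chrom = f"{chrom_prefix}{i:04d}"
        n_sites = rng.poisson(motif_density * length / 1000.0)
        for _ in range(n_sites):
            motif = motif_library[rng.integers(len(motif_library))]
            l = len(motif)
            pos = int(rng.integers(0, length - l + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = "".join(_BG_ORDER[rng.choice(4, p=motif.matrix[j])] for j in range(l))
            if strand == "-":
                site = site.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            seq[pos:pos + l] = list(site)
            rows.append({"chrom": chrom, "start": pos, "end": pos + l,
                         "motif_id": motif.motif_id, "strand": strand, "site_seq": site})
        windows.append(GenomicWindow(chrom=chrom, start=0,
                                     sequence="".join(seq), anchor=length // 2))
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_id",
                                        "strand", "site_seq"])
    return windows, sites


def simulate_track_counts(true_rates: TrackTable, seed: int = 0) -> TrackTable:
    """Poisson-sampled experimental counts from per-bin true rates."""
    if np.any(true_rates.values <= 0):
        raise ValueError("true rates must be strictly positive")
    rng = np.random.default_rng(seed)
    return TrackTable(
        track_id=true_rates.track_id,
        assay_class=true_rates.assay_class,
        values=rng.poisson(true_rates.values).astype(float),
        bin_width=true_rates.bin_width,
    )


def simulate_eqtls(
    windows: Sequence[GenomicWindow],
    sites: pd.DataFrame,
    n_pos: int,
    n_neg: int,
    seed: int,
    model: GroundTruthModel,
    track: Optional[str] = None,
    min_effect: float = 0.02,
) -> List[VariantRecord]:
    """Variants with known truth (in planted motifs) and matched negatives.

    Positives substitute a base inside a planted motif instance; their
    ``true_sign`` is the sign of the ground-truth alt-minus-ref SAD.
    Candidates whose true effect is smaller than ``min_effect`` (in
    counts over the three variant bins) are resampled, so positives play
    the role of fine-mapped eQTLs: variants with a real effect of known
    direction. Negatives substitute background positions and carry
    unknown truth.
    """
    rng = np.random.default_rng(seed)
    by_chrom = {w.chrom: w for w in windows}
    bw = model.bin_width
    if n_pos > 0 and sites.empty:
        raise ValueError("no planted sites available for positive variants")
    usable = sites[[c in by_chrom for c in sites["chrom"]]].reset_index(drop=True) \
        if not sites.empty else sites
    if n_pos > 0 and usable.empty:
        raise ValueError("no planted sites fall inside the provided windows")

    out: List[VariantRecord] = []
    rounds = 0
    # candidates are proposed and their ground-truth SADs evaluated in
    # batches (one scan per unique sequence) rather than one at a time
    while len(out) < n_pos:
        if rounds > 40:
            raise ValueError("could not place the requested positive variants "
                             "(not enough planted sites with nonzero effect)")
        rounds += 1
        want = n_pos - len(out)
        candidates: List[Tuple[GenomicWindow, int, str]] = []
        for _ in range(8 * want):
            if len(candidates) >= 2 * want:
                break
            row = usable.iloc[int(rng.integers(len(usable)))]
            window = by_chrom[row["chrom"]]
            pos = int(rng.integers(row["start"], row["end"]))
            if not (bw <= pos < window.length - bw):
                continue
            ref = window.sequence[pos]
            if ref == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            candidates.append((window, pos, alt))
        if not candidates:
            continue
        batch: List[GenomicWindow] = []
        ref_idx: Dict[str, int] = {}
        slots = []
        for window, pos, alt in candidates:
            if window.chrom not in ref_idx:
                ref_idx[window.chrom] = len(batch)
                batch.append(window)
            alt_seq = window.sequence[:pos] + alt + window.sequence[pos + 1:]
            slots.append((ref_idx[window.chrom], len(batch), pos))
            batch.append(window.with_sequence(alt_seq))
        preds = model_robust_predict(model, batch, track=track)
        n_bins = preds.shape[1]
        for (window, pos, alt), (ri, ai, _) in zip(candidates, slots):
            if len(out) >= n_pos:
                break
            b = pos // bw
            if b == 0 or b >= n_bins - 1:
                continue
            delta = float(np.sum(preds[ai, b - 1:b + 2] - preds[ri, b - 1:b + 2]))
            if abs(delta) < min_effect:  # null effect: not a usable positive
                continue
            out.append(VariantRecord(
                chrom=window.chrom, pos=pos, ref_allele=window.sequence[pos],
                alt_allele=alt, gene_id=f"gene_{window.chrom}",
                tss_distance=pos - window.anchor,
                true_sign=1 if delta > 0 else -1,
            ))

    site_spans: Dict[str, list] = {}
    if not usable.empty:
        for _, row in usable.iterrows():
            site_spans.setdefault(row["chrom"], []).append((row["start"], row["end"]))
    n_placed = 0
    tries = 0
    while n_placed < n_neg:
        if tries > 80 * max(n_neg, 1):
            raise ValueError("could not place the requested negative variants")
        tries += 1
        window = windows[int(rng.integers(len(windows)))]
        pos = int(rng.integers(bw, window.length - bw))
        if any(s <= pos < e for s, e in site_spans.get(window.chrom, [])):
            continue
        ref = window.sequence[pos]
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        out.append(VariantRecord(
            chrom=window.chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            gene_id=f"gene_{window.chrom}", tss_distance=pos - window.anchor,
            true_sign=None,
        ))
        n_placed += 1
    return out


def simulate_population(
    window: GenomicWindow,
    variants: Sequence[VariantRecord],
    n_individuals: int,
    allele_freqs: Optional[Sequence[float]] = None,
    h2: float = 0.3,
    seed: int = 0,
    model: Optional[GroundTruthModel] = None,
    track: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """A phased diploid cohort and measured expression for one gene window.

    Haplotype alleles are drawn independently at the stated frequencies
    (no linkage disequilibrium). Measured expression is the standardized
    ground-truth individual prediction scaled to variance ``h2`` plus
    Gaussian noise of variance ``1 - h2``; a cohort with no predicted
    variation yields pure noise.
    """
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_var = len(variants)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.05, 0.5, size=n_var)
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.shape != (n_var,):
        raise ValueError("need one allele frequency per variant")
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    genotypes = (rng.random((n_individuals, n_var, 2)) < freqs[None, :, None]).astype(np.int8)

    if model is None:
        raise ValueError("a ground-truth model is required to generate expression")
    from .personal import population_predictions  # lazy: personal builds haplotypes

    g = population_predictions(model, window, genotypes, variants, track=track)[0]
    sd = g.std()
    noise = rng.standard_normal(n_individuals)
    if sd == 0:
        measured = noise
    else:
        measured = math.sqrt(h2) * (g - g.mean()) / sd + math.sqrt(1 - h2) * noise
    return genotypes, measured
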