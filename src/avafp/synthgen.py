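"""Synthetic two-session cohorts with planted, group-structured avalanche
dynamics and a coupled clinical score.

Each subject owns a latent avalanche-propagation kernel: a 68 x 68 matrix of
spreading probabilities built by swapping, entry by entry, between one global
template T and a subject-specific random kernel R: each entry of K_s comes
from R with probability w_s and from T otherwise.  The mixing weight w_s
(drawn around a group mean w_g) controls how idiosyncratic the subject is —
large w lowers within-group similarity (Iothers) — while leaving the
kernel's sparsity and entry distribution untouched, so w does not leak into
test-retest similarity.  Each session perturbs the nonzero kernel entries
with zero-mean noise of amplitude eps_g — large eps lowers test-retest
stereotypy (Iself).  Group defaults order the healthy controls as most
flexible (largest eps, smallest w) and bilateral patients as most
stereotyped and idiosyncratic, the qualitative pattern the pipeline is meant
to recover.

Recordings are unit-variance white Gaussian noise plus pulse trains: at
Poisson times an avalanche starts at a random region and spreads per bin with
the kernel probabilities, rescaled so the expected offspring per active
region equals a branching parameter m (default 1.0, near-critical); active
(region, bin) positions receive a random-sign pulse of ``pulse_amplitude``
noise SDs.  A synthetic figure-recall score couples linearly to each
patient's kernel similarity to the healthy-control template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

import numba

from .avalanche import GROUPS, Recording

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "iter_cohort",
           "simulate_recording", "simulate_branching_avalanches",
           "default_roi_names"]

SESSIONS = ("test", "retest")

# Cohort sizes mirror the study population: 35 controls, 31 left and 17 right
# unilateral TLE, 20 bilateral TLE.
_DEFAULT_SIZES = {"HC": 35, "UTLE-L": 31, "UTLE-R": 17, "BTLE": 20}
_DEFAULT_W = {"HC": 0.20, "UTLE-L": 0.50, "UTLE-R": 0.50, "BTLE": 0.75}
_DEFAULT_EPS = {"HC": 0.35, "UTLE-L": 0.18, "UTLE-R": 0.18, "BTLE": 0.07}

# Table-style neuropsychological battery (mean, SD) used to dress the
# manifest; only the recall score is coupled to the planted similarity.
_BATTERY = {
    "digit_span": (5.63, 1.12),
    "corsi": (4.83, 1.05),
    "rocft_copy": (32.06, 4.83),
    "ravlt_immediate": (39.12, 9.02),
    "ravlt_delayed": (7.20, 3.23),
    "tmt_a": (33.01, 16.30),
    "tmt_b": (113.48, 72.91),
}


def default_roi_names(n_regions: int = 68) -> list[str]:
    """Placeholder cortical ROI labels in a fixed hemispheric order."""
    half = n_regions // 2
    names = [f"roi{i + 1:02d}-lh" for i in range(half)]
    names += [f"roi{i + 1:02d}-rh" for i in range(n_regions - half)]
    return names


@dataclass
class CohortSpec:
    """Generator configuration; defaults are the emulated study conditions."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    n_regions: int = 68
    fs: float = 250.0
    duration_s: float = 180.0
    kernel_idiosyncrasy: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_W)
    )
    idiosyncrasy_sd: float = 0.10
    session_jitter: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EPS)
    )
    event_rate: float = 5.0            # avalanche initiations per second
    pulse_amplitude: float = 6.0       # pulse height in noise-SD units
    branching_m: float = 1.0           # expected offspring per active region
    kernel_density: float = 0.15       # fraction of nonzero kernel entries
    max_avalanche_bins: int = 500      # hard cap on one avalanche's duration
    clinical_intercept: float = -15.0
    clinical_slope: float = 60.0       # b > 0 couples recall to HC-similarity
    clinical_noise_sd: float = 4.0
    seed: int = 0

    def validate(self, for_fingerprint: bool = False) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group label: {g!r}")
        if for_fingerprint and any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group_sizes: every group needs >= 2 subjects")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group_sizes must be nonnegative")
        for g, w in self.kernel_idiosyncrasy.items():
            if not 0 <= w <= 1:
                raise ValueError(f"kernel_idiosyncrasy[{g!r}] must lie in [0, 1]")
        for g, e in self.session_jitter.items():
            if e < 0:
                raise ValueError(f"session_jitter[{g!r}] must be >= 0")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if not 0 < self.kernel_density <= 1:
            raise ValueError("kernel_density must lie in (0, 1]")
        if self.branching_m <= 0:
            raise ValueError("branching_m must be positive")


@dataclass
class GroundTruth:
    """Latent quantities the generator planted, for recovery checks."""

    template: np.ndarray
    subject_kernels: dict[str, np.ndarray]
    session_kernels: dict[tuple[str, str], np.ndarray]
    idiosyncrasy: dict[str, float]
    template_similarity: dict[str, float]
    clinical_signal: dict[str, float]   # noiseless score component, patients
    clinical_score: dict[str, float]    # planted recall score, patients


def _random_kernel(
    rng: np.random.Generator, n: int, density: float
) -> np.ndarray:
    """Sparse nonnegative spreading kernel with entries in [0, 1]."""
    K = rng.uniform(0.0, 1.0, size=(n, n))
    K *= rng.random((n, n)) < density
    np.fill_diagonal(K, 0.0)
    return K


@numba.njit(cache=False)
def _propagate_events(
    data: np.ndarray,
    K: np.ndarray,
    starts: np.ndarray,
    amp: np.float32,
    max_bins: int,
    seed: int,
) -> None:
    """Add avalanche pulse trains to ``data`` in place.

    Each initiation seeds one region; each active region i activates region j
    at the next bin with probability K[i, j]; initiations during an ongoing
    avalanche are dropped.  Active (region, bin) positions get a random-sign
    pulse of height ``amp``.  Compiled because the bin-by-bin dependence
    cannot be vectorized.
    """
    np.random.seed(seed)
    n = K.shape[0]
    n_bins = data.shape[1]
    active = np.zeros(n, dtype=np.bool_)
    nxt = np.zeros(n, dtype=np.bool_)
    busy_until = -1
    for t0 in starts:
        if t0 <= busy_until:
            continue
        active[:] = False
        active[np.random.randint(0, n)] = True
        t = t0
        steps = 0
        n_active = 1
        while n_active > 0 and t < n_bins and steps < max_bins:
            for j in range(n):
                nxt[j] = False
            q = np.ones(n)
            for i in range(n):
                if active[i]:
                    if np.random.random() < 0.5:
                        data[i, t] += amp
                    else:
                        data[i, t] -= amp
                    for j in range(n):
                        q[j] *= 1.0 - K[i, j]
            n_active = 0
            for j in range(n):
                if np.random.random() < 1.0 - q[j]:
                    nxt[j] = True
                    n_active += 1
            active, nxt = nxt, active
            t += 1
            steps += 1
        busy_until = t - 1


def _rescale_to_m(kernel: np.ndarray, m: float) -> np.ndarray:
    """Scale so the mean row sum (expected offspring) equals m; clip to [0,1]."""
    mean_offspring = kernel.sum(axis=1).mean()
    if mean_offspring <= 0:
        raise ValueError("kernel has no positive entries")
    return np.clip(kernel * (m / mean_offspring), 0.0, 1.0)


def simulate_recording(
    kernel: np.ndarray,
    spec: CohortSpec,
    seed: int | np.random.Generator,
    subject_id: str = "sub-000",
    session: str = "test",
    group: str = "HC",
    roi_names: list[str] | None = None,
) -> Recording:
    """One session: white Gaussian background plus kernel-driven pulse trains.

    Avalanches initiate at Poisson times at a uniformly random region and
    propagate bin to bin: region j activates at t+1 with probability
    1 - prod_{i active}(1 - K[i, j]).  The kernel is first rescaled so the
    expected offspring per active region is ``spec.branching_m``.  Initiations
    that fall inside an ongoing avalanche are dropped, so planted avalanches
    never overlap.  Pulses of ``pulse_amplitude`` noise-SDs with random sign
    are added at active positions.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError("kernel must be square")
    if ((kernel < 0) | (kernel > 1)).any():
        raise ValueError("kernel entries must lie in [0, 1]")
    spec.validate()
    n = kernel.shape[0]
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_bins = int(round(spec.fs * spec.duration_s))
    data = rng.standard_normal((n, n_bins), dtype=np.float32)

    if spec.event_rate > 0 and spec.pulse_amplitude >= 0:
        K = _rescale_to_m(kernel, spec.branching_m)
        n_events = rng.poisson(spec.event_rate * spec.duration_s)
        starts = np.sort(rng.integers(0, n_bins, size=n_events)).astype(np.int64)
        _propagate_events(
            data,
            K,
            starts,
            np.float32(spec.pulse_amplitude),
            int(spec.max_avalanche_bins),
            int(rng.integers(2**31)),
        )
    return Recording(
        subject_id=subject_id,
        session=session,
        group=group,
        fs=spec.fs,
        roi_names=roi_names or default_roi_names(n),
        data=data,
    )


def simulate_branching_avalanches(
    n_avalanches: int,
    m: float = 1.0,
    n_max: int = 68,
    max_bins: int = 500,
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Event-count sequences from a Galton-Watson branching process.

    Each avalanche seeds one active unit; at every subsequent bin each active
    unit spawns Poisson(m) offspring, with the total capped at ``n_max`` (the
    number of cortical regions available to be active).  The sequence ends
    when no units remain, or after ``max_bins`` bins — the saturated critical
    process mean-reverts around the cap and would otherwise survive nearly
    forever, whereas recorded avalanches are always duration-bounded.  At
    m = 1 the process is critical, the regime whose estimated branching ratio
    should come out near 1.
    """
    if n_avalanches < 1:
        raise ValueError("n_avalanches must be >= 1")
    if m <= 0:
        raise ValueError("m must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    out = []
    for _ in range(n_avalanches):
        counts = [1]
        while counts[-1] > 0 and len(counts) < max_bins:
            nxt = int(rng.poisson(m * counts[-1]))
            counts.append(min(nxt, n_max))
        if counts[-1] == 0:
            counts = counts[:-1]
        out.append(np.asarray(counts, dtype=np.int64))
    return out


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def iter_cohort(
    spec: CohortSpec,
) -> Iterator[tuple[dict, Recording, Recording]]:
    """Yield (manifest row, test Recording, retest Recording) per subject.

    Streaming form of :func:`generate_cohort` — recordings can be consumed
    and discarded one subject at a time.  Deterministic given ``spec.seed``;
    every subject draws from an independent child stream.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_template, ss_subjects, ss_clinical = root.spawn(3)
    rng_t = np.random.default_rng(ss_template)
    template = _random_kernel(rng_t, spec.n_regions, spec.kernel_density)
    roi_names = default_roi_names(spec.n_regions)
    rng_c = np.random.default_rng(ss_clinical)

    order = [g for g in GROUPS if spec.group_sizes.get(g, 0) > 0]
    subject_streams = ss_subjects.spawn(sum(spec.group_sizes[g] for g in order))
    k = 0
    for g in order:
        w_g = spec.kernel_idiosyncrasy[g]
        eps_g = spec.session_jitter[g]
        for j in range(spec.group_sizes[g]):
            sid = f"{g}-{j + 1:03d}"
            rng_s = np.random.default_rng(subject_streams[k])
            k += 1
            w_s = float(np.clip(rng_s.normal(w_g, spec.idiosyncrasy_sd), 0.0, 1.0))
            K_rand = _random_kernel(rng_s, spec.n_regions, spec.kernel_density)
            swap = rng_s.random(template.shape) < w_s
            K_s = np.where(swap, K_rand, template)
            sim = _flat_corr(K_s, template)

            support = K_s > 0
            recs = []
            for sess in SESSIONS:
                noise = rng_s.standard_normal(K_s.shape) * support
                K_sess = np.clip(K_s + eps_g * noise, 0.0, 1.0)
                recs.append(
                    simulate_recording(
                        K_sess, spec, rng_s,
                        subject_id=sid, session=sess, group=g,
                        roi_names=roi_names,
                    )
                )

            hemisphere = {"UTLE-L": "L", "UTLE-R": "R", "BTLE": "B"}.get(g, "")
            row: dict = {
                "subject_id": sid,
                "group": g,
                "hemisphere": hemisphere,
                "gender": "F" if rng_c.random() < 0.55 else "M",
                "age": float(
                    np.clip(
                        rng_c.normal(34.9, 9.2) if g == "HC" else rng_c.normal(41.4, 17.1),
                        18, 80,
                    )
                ),
                "w_s": w_s,
                "template_similarity": sim,
            }
            if g != "HC":
                signal = spec.clinical_intercept + spec.clinical_slope * sim
                row["rocft_recall_signal"] = signal
                row["rocft_recall"] = signal + rng_c.normal(0, spec.clinical_noise_sd)
                for name, (mu, sd) in _BATTERY.items():
                    row[name] = float(rng_c.normal(mu, sd))
            yield (
                {**row, "kernel": K_s, "session_kernels": None},
                recs[0],
                recs[1],
            )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, tuple[Recording, Recording]], GroundTruth, pd.DataFrame]:
    """Materialize a full cohort: recordings, planted truth, clinical table."""
    spec.validate()
    recordings: dict[str, tuple[Recording, Recording]] = {}
    rows = []
    gt = GroundTruth(
        template=np.empty(0),
        subject_kernels={},
        session_kernels={},
        idiosyncrasy={},
        template_similarity={},
        clinical_signal={},
        clinical_score={},
    )
    root = np.random.SeedSequence(spec.seed)
    gt.template = _random_kernel(
        np.random.default_rng(root.spawn(3)[0]), spec.n_regions, spec.kernel_density
    )
    for row, rec_t, rec_r in iter_cohort(spec):
        sid = row["subject_id"]
        recordings[sid] = (rec_t, rec_r)
        gt.subject_kernels[sid] = row.pop("kernel")
        row.pop("session_kernels")
        gt.idiosyncrasy[sid] = row["w_s"]
        gt.template_similarity[sid] = row["template_similarity"]
        if "rocft_recall" in row:
            gt.clinical_signal[sid] = row["rocft_recall_signal"]
            gt.clinical_score[sid] = row["rocft_recall"]
        rows.append(
            {
                k: v
                for k, v in row.items()
                if k not in ("w_s", "rocft_recall_signal", "template_similarity")
            }
        )
    manifest = pd.DataFrame(rows).set_index("subject_id")
    return recordings, gt, manifest
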