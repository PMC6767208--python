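"""Convolutional dictionary learning of step atoms and signal embedding.

Walk signals are modelled as sparse sums of shifted copies of a few short
waveform templates (atoms), one per step shape.  The atoms are learned by
convolutional basis pursuit denoising:

    min_{x, d}  sum_s [ 1/2 || sum_m x_m * d_m - s ||_2^2
                        + lambda * sum_m || x_m ||_1 ]

with unit-norm atoms supported on ``L`` samples (0.7 s at 100 Hz by
default, an upper bound on the duration of a healthy step).  The solver
alternates single ADMM iterations of sparse coding (atoms fixed) and
dictionary update (codes fixed, coupled across signals), working in the
frequency domain where the circular-convolution subproblems are
diagonal per frequency.

Once the atoms are learned, signals are embedded for the networks by
plain (non-sparse) "same"-length convolution with each atom, producing
an m-channel encoding aligned with the raw time axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from floorgait.dataset import Dataset, EventClass, PersonStatus, Recording
from floorgait.preprocess import MonoSignal

__all__ = [
    "StepDictionary",
    "SparseCodes",
    "EmbeddedSignal",
    "cdl_objective",
    "learn_dictionary",
    "sparse_code",
    "select_num_atoms",
    "embed",
    "walk_training_filter",
]

DEFAULT_M = 3
DEFAULT_ATOM_SEC = 0.7
DEFAULT_LAMBDA = 5.0
DEFAULT_ITERS = 2000
ACTIVE_TOL = 1e-6


@dataclass
class StepDictionary:
    """m unit-norm atoms of L samples each (rows of ``atoms``)."""

    atoms: np.ndarray
    rate_hz: float = 100.0
    lambda_used: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def atom_len(self) -> int:
        return self.atoms.shape[1]

    @property
    def atom_sec(self) -> float:
        return self.atom_len / self.rate_hz

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rate_hz": self.rate_hz,
            "lambda_used": self.lambda_used,
            "atoms": self.atoms.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "StepDictionary":
        d = json.loads(Path(path).read_text())
        return cls(atoms=np.asarray(d["atoms"]), rate_hz=d["rate_hz"],
                   lambda_used=d["lambda_used"])


@dataclass
class SparseCodes:
    """Per-atom activation signals for one input signal."""

    codes: np.ndarray  # (m, T)

    def __post_init__(self) -> None:
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=float))

    @property
    def sparsity(self) -> float:
        """Fraction of entries with magnitude above the activity tolerance."""
        return float(np.mean(np.abs(self.codes) > ACTIVE_TOL))


@dataclass
class EmbeddedSignal:
    """m-channel convolution of a mono signal with the dictionary atoms."""

    channels: np.ndarray  # (m, T)
    rate_hz: float = 100.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))

    @property
    def m(self) -> int:
        return self.channels.shape[0]

    def __len__(self) -> int:
        return self.channels.shape[1]


def _as_signal_array(signals) -> list[np.ndarray]:
    out = []
    for s in signals:
        out.append(np.asarray(s.s if isinstance(s, MonoSignal) else s, dtype=float).ravel())
    return out


def cdl_objective(signals, dictionary: StepDictionary, codes_per_signal, lam: float) -> float:
    """Value of the basis-pursuit-denoising objective at the given point.

    Reconstruction uses linear convolution truncated to the signal length,
    so a code entry at sample ``t`` places an atom starting at ``t``.
    """
    sigs = _as_signal_array(signals)
    if len(sigs) != len(codes_per_signal):
        raise ValueError("signals and codes_per_signal must have equal length")
    total = 0.0
    for s, codes in zip(sigs, codes_per_signal):
        x = codes.codes if isinstance(codes, SparseCodes) else np.atleast_2d(codes)
        if x.shape[0] != dictionary.m:
            raise ValueError(f"expected {dictionary.m} code rows, got {x.shape[0]}")
        recon = np.zeros_like(s)
        for xm, dm in zip(x, dictionary.atoms):
            recon += sps.fftconvolve(xm, dm)[: s.size]
        total += 0.5 * float(np.sum((recon - s) ** 2)) + lam * float(np.sum(np.abs(x)))
    return total


def _soft(v: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)


class _CDLState:
    """Frequency-domain ADMM state shared by coding and dictionary update."""

    def __init__(self, sigs: list[np.ndarray], m: int, atom_len: int,
                 lam: float, rng: np.random.Generator):
        self.n = max(s.size for s in sigs)
        self.k = len(sigs)
        self.m = m
        self.atom_len = atom_len
        self.lam = lam
        self.s = np.zeros((self.k, self.n))
        for i, s in enumerate(sigs):
            self.s[i, : s.size] = s
        self.sf = np.fft.rfft(self.s, axis=-1)
        atoms = self._chunk_init(sigs, m, atom_len, rng)
        self.d = self._pad_atoms(atoms)
        self.df = np.fft.rfft(self.d, axis=-1)
        # sparse coding variables: (k, m, n)
        self.z = np.zeros((self.k, m, self.n))
        self.u = np.zeros_like(self.z)
        # dictionary-update variables
        self.g = self.d.copy()
        self.h = np.zeros_like(self.d)
        # penalty parameters: a coding penalty on the order of lambda keeps
        # the soft threshold (lam/rho) large enough to consolidate diffuse
        # activations without freezing the codes at zero
        self.rho = max(lam, 0.5)
        self.sigma = float(self.k)

    @staticmethod
    def _chunk_init(sigs: list[np.ndarray], m: int, atom_len: int,
                    rng: np.random.Generator, n_cand: int = 10) -> np.ndarray:
        """Initialize each atom from the highest-energy of a few random
        signal windows (a Gaussian fallback covers degenerate signals).
        A data init keeps the sparse-coding step out of the all-zero
        fixed point that a noise atom's weak correlations would create."""
        atoms = np.empty((m, atom_len))
        for j in range(m):
            best, best_e = None, -1.0
            for _ in range(n_cand):
                s = sigs[rng.integers(len(sigs))]
                if s.size <= atom_len:
                    continue
                t0 = int(rng.integers(s.size - atom_len))
                chunk = s[t0 : t0 + atom_len]
                e = float(np.sum(chunk**2))
                if e > best_e:
                    best, best_e = chunk, e
            if best is None or best_e <= 0:
                best = rng.standard_normal(atom_len)
            atom = best + 1e-3 * rng.standard_normal(atom_len)
            atoms[j] = atom / np.linalg.norm(atom)
        return atoms

    def _pad_atoms(self, atoms: np.ndarray) -> np.ndarray:
        out = np.zeros((self.m, self.n))
        out[:, : self.atom_len] = atoms
        return out

    @property
    def atoms(self) -> np.ndarray:
        a = self.g[:, : self.atom_len].copy()
        norms = np.linalg.norm(a, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return a / norms

    def coding_step(self) -> None:
        """One ADMM iteration of CBPDN with the dictionary fixed."""
        rho = self.rho
        zf = np.fft.rfft(self.z - self.u, axis=-1)
        rhs = np.conj(self.df)[None, :, :] * self.sf[:, None, :] + rho * zf
        dsq = np.sum(np.abs(self.df) ** 2, axis=0)  # per-frequency ||v||^2
        # Sherman-Morrison for (rho I + v^H v) x = rhs, v = df row vector
        vb = np.sum(self.df[None, :, :] * rhs, axis=1)  # (k, n_f)
        xf = rhs / rho - np.conj(self.df)[None, :, :] * (vb / (rho * (rho + dsq)))[:, None, :]
        x = np.fft.irfft(xf, n=self.n, axis=-1)
        self.z = _soft(x + self.u, self.lam / rho)
        self.u += x - self.z
        self._x = x

    def dict_step(self) -> None:
        """One ADMM iteration of the dictionary update with codes fixed."""
        sigma = self.sigma
        xf = np.fft.rfft(self.z, axis=-1)  # (k, m, n_f)
        rhs = np.sum(np.conj(xf) * self.sf[:, None, :], axis=0) + sigma * np.fft.rfft(
            self.g - self.h, axis=-1
        )  # (m, n_f)
        if self.m == 1:
            denom = np.sum(np.abs(xf[:, 0, :]) ** 2, axis=0) + sigma
            df = rhs / denom[None, :]
        else:
            # per-frequency m x m normal matrix: sum_k v_k^H v_k + sigma I
            a = np.einsum("kif,kjf->fij", np.conj(xf), xf)
            a += sigma * np.eye(self.m)[None, :, :]
            df = np.linalg.solve(a, rhs.T[:, :, None])[:, :, 0].T
        d = np.fft.irfft(df, n=self.n, axis=-1)
        # project onto {support in [0, L), unit norm}
        g = np.zeros_like(d)
        g[:, : self.atom_len] = d[:, : self.atom_len]
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        g /= norms
        self.g = g
        self.h += d - g
        self.d = g
        self.df = np.fft.rfft(self.d, axis=-1)

    def codes(self) -> list[SparseCodes]:
        return [SparseCodes(self.z[i].copy()) for i in range(self.k)]


def learn_dictionary(
    signals,
    m: int = DEFAULT_M,
    atom_sec: float = DEFAULT_ATOM_SEC,
    lam: float = DEFAULT_LAMBDA,
    iters: int = DEFAULT_ITERS,
    seed: int | None = None,
    rate_hz: float = 100.0,
    objective_every: int = 10,
) -> tuple[StepDictionary, list[SparseCodes]]:
    """Learn ``m`` unit-norm step atoms by alternating ADMM.

    Returns the iterate with the lowest objective value seen (evaluated
    every ``objective_every`` outer iterations and at the end), which is
    never worse than the random initialization.  Deterministic given
    ``seed``.
    """
    sigs = _as_signal_array(signals)
    if not sigs:
        raise ValueError("need at least one signal")
    atom_len = int(round(atom_sec * rate_hz))
    if atom_len < 1 or m < 1 or iters < 1 or lam < 0:
        raise ValueError("invalid dictionary-learning parameters")
    if min(s.size for s in sigs) < atom_len:
        raise ValueError("atom length exceeds the shortest signal")

    rng = np.random.default_rng(seed)
    state = _CDLState(sigs, m, atom_len, lam, rng)

    def snapshot():
        dic = StepDictionary(state.atoms, rate_hz=rate_hz, lambda_used=lam)
        codes = state.codes()
        return dic, codes, cdl_objective(sigs, dic, codes, lam)

    best_dict, best_codes, best_obj = snapshot()  # random init, zero codes
    for it in range(1, iters + 1):
        state.coding_step()
        state.dict_step()
        if it % objective_every == 0 or it == iters:
            dic, codes, obj = snapshot()
            if obj <= best_obj:
                best_dict, best_codes, best_obj = dic, codes, obj
    return best_dict, best_codes


def sparse_code(
    signals,
    dictionary: StepDictionary,
    lam: float | None = None,
    iters: int = 100,
) -> list[SparseCodes]:
    """Sparse-code signals against a fixed dictionary (CBPDN via ADMM)."""
    sigs = _as_signal_array(signals)
    lam = dictionary.lambda_used if lam is None else lam
    state = _CDLState(sigs, dictionary.m, dictionary.atom_len, lam,
                      np.random.default_rng(0))
    state.d = state._pad_atoms(dictionary.atoms)
    state.df = np.fft.rfft(state.d, axis=-1)
    for _ in range(iters):
        state.coding_step()
    return state.codes()


def select_num_atoms(
    signals,
    candidate_ms,
    folds: int = 3,
    lam: float = DEFAULT_LAMBDA,
    iters: int = 200,
    seed: int | None = None,
    atom_sec: float = DEFAULT_ATOM_SEC,
    rate_hz: float = 100.0,
    sparsity_weight: float = 0.01,
) -> int:
    """Choose the atom count by k-fold cross-validation.

    For each candidate ``m`` a dictionary is trained on the training folds
    and the held-out signals are sparse-coded against it.  The score is the
    relative held-out reconstruction error plus ``sparsity_weight`` times
    the mean number of active coefficients per sample: validation
    reconstruction drives the choice (too few atoms reconstruct poorly,
    too many overfit the training folds), with a light parsimony penalty
    on dense representations breaking near-ties toward fewer atoms.
    """
    candidate_ms = sorted(set(int(m) for m in candidate_ms))
    if not candidate_ms:
        raise ValueError("candidate_ms must be non-empty")
    sigs = _as_signal_array(signals)
    if len(sigs) < folds:
        raise ValueError("need at least as many signals as folds")
    if len(candidate_ms) == 1:
        return candidate_ms[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sigs))
    fold_of = np.arange(len(sigs)) % folds
    scores: dict[int, float] = {}
    for m in candidate_ms:
        fold_scores = []
        for f in range(folds):
            train = [sigs[i] for i, fo in zip(order, fold_of) if fo != f]
            val = [sigs[i] for i, fo in zip(order, fold_of) if fo == f]
            dic, _ = learn_dictionary(train, m=m, atom_sec=atom_sec, lam=lam,
                                      iters=iters, seed=seed, rate_hz=rate_hz)
            codes = sparse_code(val, dic, lam=lam, iters=300)
            err = 0.0
            energy = 0.0
            active = 0.0
            n_samp = 0
            for s, c in zip(val, codes):
                recon = np.zeros(c.codes.shape[1])
                for xm, dm in zip(c.codes, dic.atoms):
                    recon += sps.fftconvolve(xm, dm)[: recon.size]
                err += float(np.sum((recon[: s.size] - s) ** 2))
                energy += float(np.sum(s**2))
                active += float(np.sum(np.abs(c.codes) > ACTIVE_TOL))
                n_samp += s.size
            fold_scores.append(err / max(energy, 1e-12)
                               + sparsity_weight * active / max(n_samp, 1))
        scores[m] = float(np.mean(fold_scores))
    return min(candidate_ms, key=lambda m: (scores[m], m))


def embed(s: MonoSignal | np.ndarray, dictionary: StepDictionary) -> EmbeddedSignal:
    """Embed a mono signal as its "same"-length convolution with each atom."""
    if isinstance(s, MonoSignal):
        x, rate, sid = s.s, s.rate_hz, s.source_id
    else:
        x, rate, sid = np.asarray(s, dtype=float).ravel(), dictionary.rate_hz, ""
    if x.size < dictionary.atom_len:
        raise ValueError("signal shorter than the dictionary atoms")
    channels = np.stack([np.convolve(x, dm, mode="same") for dm in dictionary.atoms])
    return EmbeddedSignal(channels=channels, rate_hz=rate, source_id=sid)


def walk_training_filter(rec: Recording) -> bool:
    """Signals suitable for dictionary / step-proposal training: clean
    single-person staff walks."""
    a = rec.annotation
    return (a.event_class is EventClass.WALK_SINGLE
            and a.person_status is PersonStatus.STAFF)
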