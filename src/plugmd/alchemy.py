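"""Dual-topology alchemical transformations and MBAR free-energy analysis.

The mixed Hamiltonian interpolates linearly between a coupled state A and
a decoupled state B in which two particle groups no longer interact:

    U(lambda) = lambda * U_A + (1 - lambda) * (U_B1({j}) + U_B2({i}))

No softcore modification is applied; the default lambda ladder is densely
spaced near 0 to keep neighbouring states overlapping where the decoupled
end is approached.  Free energies across the ladder are estimated with the
multistate Bennett acceptance ratio (MBAR): the self-consistent equations
are solved by iteration with Newton refinement, uncertainties come from
the asymptotic covariance, and the overlap matrix O_ij (the probability of
observing a sample from state i in state j) diagnoses ladder quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB
from .integrators import Trajectory, integrate_nvt, maxwell_boltzmann_velocities
from .potentials.base import PotentialModel
from .system import ParticleSystem

__all__ = [
    "AlchemicalHamiltonian", "LambdaSchedule", "DEFAULT_LAMBDA_SCHEDULE",
    "ReducedEnergyMatrix", "MBARResult", "MBARConvergenceError",
    "alchemical_energy", "run_lambda_ladder", "mbar_solve",
    "overlap_matrix", "convergence_series", "hydration_free_energy",
]

#: Ten-state ladder, densely spaced near the decoupled end.
DEFAULT_LAMBDA_SCHEDULE = (0.0, 0.01, 0.03, 0.05, 0.08, 0.12, 0.2, 0.4, 0.7, 1.0)


class MBARConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(f"MBAR did not converge in {max_iter} iterations "
                         f"(final residual {residual:.3e})")


@dataclass
class LambdaSchedule:
    """Strictly increasing lambda values spanning [0, 1]."""
    values: tuple[float, ...] = DEFAULT_LAMBDA_SCHEDULE

    def __post_init__(self):
        v = tuple(float(x) for x in self.values)
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("lambda values must be strictly increasing")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must include both endpoints 0 and 1")
        self.values = v

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


class AlchemicalHamiltonian(PotentialModel):
    """U(lambda) = lambda*U_A + (1-lambda)*(U_B1 + U_B2).

    ``u_full``, ``u_env`` and ``u_solute`` must each return full-size force
    arrays (region terms for the two decoupled groups).  ``group_i``
    (solute) and ``group_j`` (environment) must be disjoint and cover the
    system.
    """

    def __init__(self, lambda_: float, u_full: PotentialModel,
                 u_env: PotentialModel, u_solute: PotentialModel,
                 group_i, group_j, n_total: int | None = None):
        if not 0.0 <= lambda_ <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        gi = set(int(x) for x in group_i)
        gj = set(int(x) for x in group_j)
        if gi & gj:
            raise ValueError("solute and environment groups overlap")
        if n_total is not None and gi | gj != set(range(n_total)):
            raise ValueError("groups must cover all particles")
        self.lambda_ = float(lambda_)
        self.u_full, self.u_env, self.u_solute = u_full, u_env, u_solute
        self.group_i = np.asarray(sorted(gi))
        self.group_j = np.asarray(sorted(gj))

    @property
    def cutoff(self):
        cuts = [t.cutoff for t in (self.u_full, self.u_env, self.u_solute)
                if t.cutoff is not None]
        return max(cuts) if cuts else None

    @cutoff.setter
    def cutoff(self, value):  # pragma: no cover
        pass

    def _compute(self, pos, box):
        lam = self.lambda_
        e = 0.0
        f = np.zeros_like(pos)
        if lam > 0.0:
            ea, fa = self.u_full.evaluate(pos, box)
            e += lam * ea
            f += lam * fa
        if lam < 1.0:
            e1, f1 = self.u_env.evaluate(pos, box)
            e2, f2 = self.u_solute.evaluate(pos, box)
            e += (1.0 - lam) * (e1 + e2)
            f += (1.0 - lam) * (f1 + f2)
        return e, f


def alchemical_energy(hamiltonian: AlchemicalHamiltonian, positions,
                      box=None) -> tuple[float, np.ndarray]:
    """Energy and forces of the mixed Hamiltonian at its lambda."""
    return hamiltonian.evaluate(positions, box)


@dataclass
class ReducedEnergyMatrix:
    """u[k, n] = beta * U_k(x_n) for all samples n and states k."""
    u: np.ndarray                 # (K, N_total)
    n_k: np.ndarray               # samples contributed by each state
    temperature: float
    lambdas: tuple[float, ...] | None = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u.ndim != 2 or self.u.shape[1] != int(self.n_k.sum()):
            raise ValueError("matrix shape inconsistent with N_k")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("reduced energies must be finite")

    def to_csv(self, path, sidecar_path=None) -> None:
        """Wide CSV (rows = states) plus a JSON sidecar of metadata."""
        import json
        from pathlib import Path
        pd.DataFrame(self.u).to_csv(path, index=False, header=False)
        sidecar = sidecar_path or str(path) + ".json"
        Path(sidecar).write_text(json.dumps({
            "N_k": self.n_k.tolist(), "temperature": self.temperature,
            "lambda": None if self.lambdas is None else list(self.lambdas)}))

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "ReducedEnergyMatrix":
        import json
        from pathlib import Path
        u = pd.read_csv(path, header=None).to_numpy(dtype=float)
        meta = json.loads(Path(sidecar_path or str(path) + ".json").read_text())
        lam = meta.get("lambda")
        return cls(u, np.asarray(meta["N_k"]), meta["temperature"],
                   None if lam is None else tuple(lam))


@dataclass
class MBARResult:
    """Converged MBAR estimate.

    ``f_k`` are dimensionless per-state free energies with f_0 pinned to
    0; ``theta`` is the asymptotic covariance of the f_k; ``overlap`` the
    K x K overlap matrix.
    """
    f_k: np.ndarray
    theta: np.ndarray
    overlap: np.ndarray
    temperature: float
    n_k: np.ndarray
    n_iterations: int
    final_residual: float

    def delta_f(self, i: int = 0, j: int = -1) -> tuple[float, float]:
        """Dimensionless free-energy difference f_j - f_i and its SE."""
        var = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return float(self.f_k[j] - self.f_k[i]), float(np.sqrt(max(var, 0.0)))

    def delta_G(self, i: int = 0, j: int = -1) -> tuple[float, float]:
        """Free-energy difference in kJ/mol between states i and j."""
        df, se = self.delta_f(i, j)
        kt = KB * self.temperature
        return df * kt, se * kt


def _mbar_weights(u: np.ndarray, f: np.ndarray, n_k: np.ndarray):
    """Normalized weights W_nk (N, K) with sum_k N_k W_nk = 1."""
    log_num = f[:, None] - u                     # (K, N)
    log_denom = logsumexp(np.log(n_k)[:, None] + log_num, axis=0)  # (N,)
    return np.exp(log_num - log_denom).T         # (N, K)


def mbar_solve(u: ReducedEnergyMatrix | np.ndarray,
               n_k: np.ndarray | None = None, tol: float = 1e-8,
               max_iter: int = 10000, temperature: float = 300.0
               ) -> MBARResult:
    """Solve the MBAR self-consistent equations.

    Accepts either a :class:`ReducedEnergyMatrix` or a raw (K, N) array
    with explicit ``n_k``.  Convergence is measured by the maximum
    normalized-weight residual ``max_k |sum_n W_nk - 1|``.
    """
    if isinstance(u, ReducedEnergyMatrix):
        n_k = u.n_k
        temperature = u.temperature
        umat = u.u
    else:
        umat = np.asarray(u, dtype=float)
        if n_k is None:
            raise ValueError("n_k required with a raw matrix")
        n_k = np.asarray(n_k, dtype=int)
    K, N = umat.shape
    if K < 2:
        raise ValueError("MBAR needs at least two states")
    sampled = n_k > 0
    if not np.all(sampled):
        raise ValueError("every state must contribute samples (N_k > 0)")

    # stabilise: per-sample shift leaves free-energy differences unchanged
    shift = umat.min(axis=0)
    umat = umat - shift[None, :]
    log_nk = np.log(n_k)

    def residual(f):
        W = _mbar_weights(umat, f, n_k)
        return float(np.max(np.abs(W.sum(axis=0) - 1.0))), W

    f = np.zeros(K)
    it = 0
    res, W = residual(f)
    while res > tol and it < max_iter:
        # self-consistent sweep
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - umat, axis=0)
        f = -logsumexp(-umat - log_denom[None, :], axis=1)
        f -= f[0]
        it += 1
        res, W = residual(f)
        if res < 1e-2 or it % 20 == 0:
            # Newton refinement on f_1..f_{K-1}
            for _ in range(5):
                g = n_k * (W.sum(axis=0) - 1.0)
                WN = W * n_k[None, :]
                H = np.diag(n_k * W.sum(axis=0)) - WN.T @ WN
                try:
                    step = np.linalg.solve(H[1:, 1:], g[1:])
                except np.linalg.LinAlgError:
                    break
                f_try = f.copy()
                f_try[1:] -= step
                res_try, W_try = residual(f_try)
                it += 1
                if not np.isfinite(res_try) or res_try > res:
                    break
                f, res, W = f_try, res_try, W_try
                if res < tol:
                    break
    if res > tol:
        raise MBARConvergenceError(res, max_iter)

    theta = _asymptotic_covariance(W, n_k)
    overlap = (W.T @ W) * n_k[None, :]
    return MBARResult(f_k=f, theta=theta, overlap=overlap,
                      temperature=temperature, n_k=n_k,
                      n_iterations=it, final_residual=res)


def _asymptotic_covariance(W: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the f_k from the weight matrix (SVD form)."""
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    S = np.diag(s)
    inner = np.eye(len(s)) - S @ V.T @ np.diag(n_k.astype(float)) @ V @ S
    theta = V @ S @ np.linalg.pinv(inner, rcond=1e-10) @ S @ V.T
    return theta


def overlap_matrix(result: MBARResult) -> np.ndarray:
    """K x K overlap matrix O_ij; rows sum to 1."""
    return result.overlap


def run_lambda_ladder(system: ParticleSystem, hamiltonian_factory,
                      schedule: LambdaSchedule | None = None,
                      T: float = 300.0, dt: float = 0.0002,
                      steps_per_state: int = 5000, save_every: int = 100,
                      seed: int = 0, burn_in_fraction: float = 0.1,
                      thermostat: str = "langevin", coupling: float = 1.0,
                      ) -> tuple[list[Trajectory], ReducedEnergyMatrix]:
    """Simulate every lambda state and build the reduced-energy matrix.

    ``hamiltonian_factory(lam)`` must return the mixed Hamiltonian at that
    lambda.  Each state starts from a fresh copy of ``system`` with
    Maxwell-Boltzmann velocities; the first ``burn_in_fraction`` of saved
    frames is discarded as equilibration.  Every retained frame is then
    re-evaluated under all K states.  Deterministic for fixed ``seed``.
    """
    schedule = schedule or LambdaSchedule()
    lambdas = tuple(schedule)
    hams = [hamiltonian_factory(lam) for lam in lambdas]
    beta = 1.0 / (KB * T)
    seeds = np.random.SeedSequence(seed).spawn(len(lambdas))

    trajectories: list[Trajectory] = []
    kept_frames: list[np.ndarray] = []
    n_k = []
    for k, (lam, ham) in enumerate(zip(lambdas, hams)):
        sys_k = system.copy()
        rng = np.random.default_rng(seeds[k])
        sys_k.velocities = maxwell_boltzmann_velocities(sys_k.masses, T, rng)
        state_seed = int(rng.integers(2**31 - 1))
        try:
            traj, _ = integrate_nvt(sys_k, ham, dt, steps_per_state,
                                    thermostat=thermostat, T=T,
                                    coupling=coupling, seed=state_seed,
                                    save_every=save_every,
                                    record_every=max(save_every, 1))
        except Exception as exc:
            raise RuntimeError(f"lambda state {k} (lambda={lam}) failed: "
                               f"{exc}") from exc
        trajectories.append(traj)
        skip = int(np.ceil(burn_in_fraction * traj.n_frames))
        frames = traj.frames[skip:]
        kept_frames.append(np.stack(frames))
        n_k.append(len(frames))

    box = system.box if np.all(system.box > 0) else None
    all_frames = np.concatenate(kept_frames, axis=0)
    umat = np.empty((len(lambdas), len(all_frames)))
    for k, ham in enumerate(hams):
        for n, frame in enumerate(all_frames):
            umat[k, n] = beta * ham.evaluate(frame, box)[0]
    return trajectories, ReducedEnergyMatrix(umat, np.asarray(n_k), T, lambdas)


def convergence_series(u: ReducedEnergyMatrix,
                       fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
                       tol: float = 1e-8) -> pd.DataFrame:
    """Endpoint free-energy difference vs growing trajectory prefixes.

    For each fraction the first ``floor(fraction * N_k)`` samples of every
    state are analysed; returns one (delta_G, SE) row per prefix.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if len(fractions) < 2:
        raise ValueError("need at least two prefix points")
    offsets = np.concatenate([[0], np.cumsum(u.n_k)])
    rows = []
    for frac in fractions:
        m_k = np.maximum(1, (frac * u.n_k).astype(int))
        cols = np.concatenate([np.arange(offsets[k], offsets[k] + m_k[k])
                               for k in range(len(u.n_k))])
        sub = ReducedEnergyMatrix(u.u[:, cols], m_k, u.temperature, u.lambdas)
        result = mbar_solve(sub, tol=tol)
        dg, se = result.delta_G(0, -1)
        rows.append({"fraction": frac, "n_samples": int(m_k.sum()),
                     "delta_G_kjmol": dg, "se_kjmol": se})
    return pd.DataFrame(rows)


def hydration_free_energy(result: MBARResult,
                          lambdas: tuple[float, ...]) -> tuple[float, float]:
    """Solvation-convention free energy, kJ/mol.

    The decoupling free energy runs from the coupled state (lambda = 1) to
    the decoupled state (lambda = 0); the hydration (solvation) free
    energy is its negative.
    """
    lambdas = tuple(lambdas)
    i_coupled = lambdas.index(1.0)
    i_decoupled = lambdas.index(0.0)
    dg, se = result.delta_G(i_coupled, i_decoupled)
    return -dg, se
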