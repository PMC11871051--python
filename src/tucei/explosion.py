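"""Instantaneous point-charge Coulomb explosion of a molecular geometry.

Model: at t = 0 every atom of the given geometry becomes a point ion with
the assigned charge (default +1 each), and the fragments then move under
purely Coulombic pairwise repulsion with Newtonian dynamics.  The
integration runs until the residual potential energy is a negligible
fraction of the total energy, at which point the momenta are asymptotic.

By construction this instantaneous model converts the full initial Coulomb
energy into kinetic energy release, which overestimates real ion kinetic
energies; normalized-momentum representations (see :mod:`tucei.frames`)
largely cancel that overestimate.

Dynamics run in Hartree atomic units.  Many near-identical geometries (a
thermal ensemble, trajectory frames) can be exploded together in one
batched integration, which is how the delay-scan pipeline stays fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    AMU_TO_ME,
    ANGSTROM_TO_BOHR,
    HARTREE_TO_EV,
)
from .geometry import Geometry


class ConvergenceError(RuntimeError):
    """Integration failed to reach asymptotic momenta within max_time."""


@dataclass
class IntegratorConfig:
    """Numerical controls for the explosion integrator.

    pe_tolerance:
        Terminate once |residual potential| <= pe_tolerance * total energy.
    rtol, atol:
        Local error control of the embedded Dormand-Prince (RK45) scheme.
    max_time, max_steps:
        Hard limits (atomic time units / accepted steps) before the run is
        declared non-convergent.
    initial_velocities:
        Optional per-atom velocities in a.u. (default: explosion from rest).
    """

    pe_tolerance: float = 1e-5
    rtol: float = 1e-8
    atol: float = 1e-10
    max_time: float = 1e12
    max_steps: int = 100_000
    first_step: float = 1.0
    initial_velocities: np.ndarray | None = None

    def __post_init__(self):
        if self.pe_tolerance <= 0:
            raise ValueError("pe_tolerance must be > 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")


@dataclass
class ExplosionResult:
    """Asymptotic per-ion momenta and diagnostics for one exploded geometry."""

    momenta: np.ndarray            # (n_atoms, 3), a.u.
    species: list[str]
    site_labels: list[str]
    kinetic_energies_hartree: np.ndarray
    residual_pe_fraction: float
    initial_coulomb_energy: float  # Hartree
    time: float | None = None      # fs timestamp of the source frame
    n_steps: int = 0
    final_positions_bohr: np.ndarray | None = None

    @property
    def kinetic_energies_ev(self) -> np.ndarray:
        return self.kinetic_energies_hartree * HARTREE_TO_EV

    def momentum(self, site_label: str) -> np.ndarray:
        return self.momenta[self.site_labels.index(site_label)]

    @property
    def total_kinetic_energy_ev(self) -> float:
        """Kinetic energy release of the event, eV."""
        return float(self.kinetic_energies_hartree.sum() * HARTREE_TO_EV)


def _charge_array(g: Geometry, charges) -> np.ndarray:
    if charges is None:
        return np.ones(g.n_atoms)
    q = np.asarray(charges, dtype=float)
    if q.shape != (g.n_atoms,):
        raise ValueError(f"charge vector shape {q.shape} does not match "
                         f"{g.n_atoms} atoms")
    return q


def coulomb_energy(g: Geometry, charges=None) -> float:
    """Total Coulomb energy sum_{i<j} q_i q_j / r_ij in Hartree."""
    q = _charge_array(g, charges)
    x = g.positions * ANGSTROM_TO_BOHR
    diff = x[:, None, :] - x[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(g.n_atoms, 1)
    rij = r[iu]
    if np.any(rij == 0.0):
        i, j = iu[0][rij == 0.0][0], iu[1][rij == 0.0][0]
        raise ValueError(
            f"coincident atoms {g.site_labels[i]} and {g.site_labels[j]}: "
            "Coulomb energy singular")
    return float(np.sum(q[iu[0]] * q[iu[1]] / rij))


# ---------------------------------------------------------------------------
# batched RK45 (Dormand-Prince) on the N-body Coulomb problem

_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784,
                   11 / 84, 0.0])
_DP_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                   -92097 / 339200, 187 / 2100, 1 / 40])


class _PairKernel:
    """Precomputed pair list and incidence matrix for the Coulomb forces.

    For N atoms the N(N-1)/2 unordered pairs are enumerated once; per force
    evaluation only (B, n_pairs, 3) temporaries are built and the per-pair
    forces are scattered back to atoms with a single matmul against the
    signed incidence matrix.
    """

    def __init__(self, n: int, q: np.ndarray):
        ii, jj = np.triu_indices(n, 1)
        self.i, self.j = ii, jj
        self.qq = q[ii] * q[jj]                     # (n_pairs,)
        inc = np.zeros((n, len(ii)))
        inc[ii, np.arange(len(ii))] = 1.0           # force on i along +d_ij
        inc[jj, np.arange(len(ii))] = -1.0
        self.inc = inc

    def __call__(self, x: np.ndarray):
        """x: (B, N, 3) bohr -> (force (B, N, 3), potential (B,))."""
        d = x[:, self.i, :] - x[:, self.j, :]       # (B, P, 3)
        r2 = np.einsum("bpk,bpk->bp", d, d)
        inv_r = 1.0 / np.sqrt(r2)
        pot = (self.qq[None, :] * inv_r).sum(axis=1)
        w = self.qq[None, :] * inv_r ** 3           # (B, P)
        fp = w[:, :, None] * d                      # per-pair force on i
        force = np.einsum("np,bpk->bnk", self.inc, fp)
        return force, pot


def _explode_batch(positions_ang: np.ndarray, q: np.ndarray,
                   masses_amu: np.ndarray, cfg: IntegratorConfig):
    """Integrate a batch of explosions to asymptotic momenta.

    positions_ang: (B, N, 3) in Angstrom.  Returns (momenta (B, N, 3) a.u.,
    residual_fractions (B,), initial potentials (B,), accepted steps).
    """
    x = np.asarray(positions_ang, dtype=float) * ANGSTROM_TO_BOHR
    b, n, _ = x.shape
    m = masses_amu * AMU_TO_ME                            # (N,) electron masses

    if cfg.initial_velocities is not None:
        v = np.asarray(cfg.initial_velocities, dtype=float)
        v = np.broadcast_to(v, (b, n, 3)).copy()
    else:
        v = np.zeros_like(x)

    kernel = _PairKernel(n, q)
    force0, pot0 = kernel(x)
    ke0 = 0.5 * np.einsum("bnk,n->b", v * v, m)
    e_total = pot0 + ke0
    if np.any(e_total <= 0):
        raise ValueError("non-positive total energy; explosion undefined")

    inv_m = 1.0 / m[None, :, None]
    h = cfg.first_step
    t = 0.0
    steps = 0
    k_x = [None] * 7
    k_v = [None] * 7
    acc_cur = force0 * inv_m
    pot = pot0
    while not np.all(np.abs(pot) <= cfg.pe_tolerance * e_total):
        if t > cfg.max_time or steps > cfg.max_steps:
            frac = np.abs(pot) / e_total
            raise ConvergenceError(
                f"explosion not converged: t={t:.3g} au, {steps} steps, "
                f"worst residual PE fraction {frac.max():.3g} "
                f"(tolerance {cfg.pe_tolerance:g})")
        # one adaptive Dormand-Prince step shared across the batch
        while True:
            k_x[0], k_v[0] = v, acc_cur
            for s in range(1, 7):
                xi = x.copy()
                vi = v.copy()
                for j, a in enumerate(_DP_A[s]):
                    if a != 0.0:
                        xi += h * a * k_x[j]
                        vi += h * a * k_v[j]
                fs, pot_s = kernel(xi)
                k_x[s], k_v[s] = vi, fs * inv_m
            # stage 7's abscissa is the RK5 solution itself (FSAL), so the
            # last stage evaluation already gives pot and acc at the new point
            pot5 = pot_s
            x5 = x + h * sum(bc * kk for bc, kk in zip(_DP_B5, k_x) if bc)
            v5 = v + h * sum(bc * kk for bc, kk in zip(_DP_B5, k_v) if bc)
            err_x = h * sum((b5 - b4) * kk for b5, b4, kk
                            in zip(_DP_B5, _DP_B4, k_x))
            err_v = h * sum((b5 - b4) * kk for b5, b4, kk
                            in zip(_DP_B5, _DP_B4, k_v))
            scale_x = cfg.atol + cfg.rtol * np.maximum(np.abs(x), np.abs(x5))
            scale_v = cfg.atol + cfg.rtol * np.maximum(np.abs(v), np.abs(v5))
            err = max(np.max(np.abs(err_x) / scale_x),
                      np.max(np.abs(err_v) / scale_v))
            if err <= 1.0 or h <= 1e-12:
                t += h
                x, v = x5, v5
                acc_cur, pot = k_v[6], pot5
                h *= min(5.0, 0.9 * (1.0 / max(err, 1e-16)) ** 0.2)
                steps += 1
                break
            h *= max(0.1, 0.9 * (1.0 / err) ** 0.2)

    momenta = v * m[None, :, None]
    return momenta, np.abs(pot) / e_total, pot0, steps, x


def explode(g: Geometry, charges=None,
            cfg: IntegratorConfig | None = None) -> ExplosionResult:
    """Explode one geometry into singly charged atomic fragments.

    Every atom is initialized at its position with its assigned charge
    (default +1) and zero velocity, and Newton's equations of motion are
    integrated under pairwise Coulomb repulsion until the momenta are
    asymptotic.
    """
    return explode_ensemble([g], charges=charges, cfg=cfg)[0]


def explode_ensemble(geoms: list[Geometry], charges=None,
                     cfg: IntegratorConfig | None = None
                     ) -> list[ExplosionResult]:
    """Explode many same-composition geometries in one batched integration.

    All geometries must share the atom ordering of the first; near-identical
    members (thermal ensembles, trajectory frames) integrate efficiently
    under the shared adaptive step.
    """
    if not geoms:
        raise ValueError("empty geometry list")
    cfg = cfg or IntegratorConfig()
    ref = geoms[0]
    q = _charge_array(ref, charges)
    for g in geoms[1:]:
        if g.site_labels != ref.site_labels or g.elements != ref.elements:
            raise ValueError("all geometries in a batch must share atom order")
    pos = np.stack([g.positions for g in geoms])
    momenta, resid, pot0, steps, xf = _explode_batch(pos, q, ref.masses_amu, cfg)
    m_me = ref.masses_amu * AMU_TO_ME
    out = []
    for i, g in enumerate(geoms):
        ke = 0.5 * np.sum(momenta[i] ** 2, axis=1) / m_me
        out.append(ExplosionResult(
            momenta=momenta[i],
            species=g.elements,
            site_labels=g.site_labels,
            kinetic_energies_hartree=ke,
            residual_pe_fraction=float(resid[i]),
            initial_coulomb_energy=float(pot0[i]),
            time=g.time,
            n_steps=steps,
            final_positions_bohr=xf[i],
        ))
    return out


def explode_trajectory(traj, charges=None,
                       cfg: IntegratorConfig | None = None
                       ) -> list[tuple[float, ExplosionResult]]:
    """Explode every frame of a trajectory independently, in frame order."""
    frames = list(traj.frames) if hasattr(traj, "frames") else list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    results = explode_ensemble(frames, charges=charges, cfg=cfg)
    return [(f.time, r) for f, r in zip(frames, results)]
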