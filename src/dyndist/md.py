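"""Constrained velocity-Verlet MD on the dynamic-distance coordinate.

The dynamic distance D is a single scalar holonomic constraint, so the
SHAKE linear system is 1×1: the position-level Lagrange multiplier is
found by a damped Newton iteration on

    g(λ) = D( q' + λ·(dt²/2)·M⁻¹·∇D(q₀) ) − D_target

to |g| ≤ tol (default 1e-8 Å), and a RATTLE velocity projection
enforces dD/dt = 0 after every step.  The reported multiplier F is the
force amplitude with which the constraint acts on the atoms
(force = +F·∇D); with this sign convention the window average ⟨F⟩ is
the free-energy derivative dA/dD, so integrating ⟨F⟩ from small to
large D yields a positive dissociation free energy for a bound system.

Thermostats: Nosé–Hoover chains (default chain length 3, time constant
1 ps, as used for the production NVT runs this package emulates) and a
Langevin option for small fixtures where chain thermostats are poorly
ergodic.  NPT barostatting of explicit solvent is out of toy scope and
replaced by NVT throughout.  Simulated annealing multiplies the
thermostat target by a fixed factor (0.99) on a fixed rescale interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EUNIT, FCONV, KB
from .cv import DynamicDistanceSpec, dynamic_distance, dynamic_distance_gradient
from .toymodel import Configuration, ToyTopology, energy_and_forces

__all__ = [
    "ConstraintState",
    "NoseHooverChain",
    "Langevin",
    "MDResult",
    "ConstraintError",
    "initialize_velocities",
    "kinetic_energy",
    "instantaneous_temperature",
    "step_constrained",
    "run_nvt",
    "anneal",
    "zip_up",
    "zip_schedule",
]


class ConstraintError(RuntimeError):
    """Constraint solver failed to converge; carries diagnostics."""

    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"constraint iteration did not converge: |g| = {residual:.3e} Å "
            f"after {iterations} iterations"
        )
        self.residual = residual
        self.iterations = iterations


@dataclass
class ConstraintState:
    """Target value and solver settings for the dynamic-distance constraint."""

    spec: DynamicDistanceSpec
    target_D: float
    tol: float = 1e-8
    max_iter: int = 50
    lambda_trace: list = field(default_factory=list)


def kinetic_energy(conf: Configuration) -> float:
    """Kinetic energy, kJ/mol."""
    v = conf.velocities[~conf.frozen]
    m = conf.masses[~conf.frozen]
    return 0.5 * float(np.sum(m * np.sum(v * v, axis=1))) * EUNIT


def instantaneous_temperature(conf: Configuration, n_f: int) -> float:
    """Kinetic temperature 2·KE/(n_f·kB), K."""
    return 2.0 * kinetic_energy(conf) / (n_f * KB)


def default_n_f(
    conf: Configuration,
    constrained: bool = False,
    remove_com: bool = True,
) -> int:
    """Degrees of freedom: 3·N_active − COM (if removed) − constraint."""
    n = int(np.sum(~conf.frozen))
    n_f = 3 * n
    if remove_com and n > 1:
        n_f -= 3
    if constrained:
        n_f -= 1
    return max(n_f, 1)


def initialize_velocities(
    conf: Configuration,
    T: float,
    rng: np.random.Generator,
    spec: DynamicDistanceSpec | None = None,
    remove_com: bool = True,
) -> None:
    """Maxwell–Boltzmann velocities at temperature ``T`` (in place).

    Centre-of-mass motion is removed, the component along the dynamic
    distance is projected out when a constraint spec is given, and the
    result is rescaled to the exact target temperature.
    """
    active = ~conf.frozen
    kT_int = KB * T / EUNIT
    v = rng.normal(size=conf.positions.shape) * np.sqrt(
        kT_int / conf.masses
    )[:, None]
    v[~active] = 0.0
    if remove_com and active.sum() > 1:
        m = conf.masses[active]
        v[active] -= np.average(v[active], axis=0, weights=m)
    if spec is not None:
        grad = dynamic_distance_gradient(spec, conf.positions)
        minv_grad = grad / conf.masses[:, None]
        denom = float(np.sum(grad * minv_grad))
        if denom > 0:
            v -= (np.sum(grad * v) / denom) * minv_grad
    conf.velocities = v
    n_f = default_n_f(conf, spec is not None, remove_com)
    if T > 0:
        t_now = instantaneous_temperature(conf, n_f)
        if t_now > 0:
            conf.velocities *= np.sqrt(T / t_now)


# ----------------------------------------------------------------------
# thermostats

_SY7 = np.array(
    [
        0.784513610477560,
        0.235573213359357,
        -1.17767998417887,
        1.31518632068391,
        -1.17767998417887,
        0.235573213359357,
        0.784513610477560,
    ]
)


class NoseHooverChain:
    """Nosé–Hoover chain thermostat (length 3, time constant 1 ps default).

    Integrated with a 7-point Suzuki–Yoshida decomposition; couples to
    all active particle velocities via a global scale factor, so the
    RATTLE velocity condition dD/dt = 0 is preserved exactly.
    """

    def __init__(
        self, target_T: float, chain_length: int = 3, tau: float = 1000.0
    ):
        if chain_length < 1:
            raise ValueError("chain length must be >= 1")
        self.target_T = float(target_T)
        self.M = int(chain_length)
        self.tau = float(tau)
        self.xi = np.zeros(self.M)
        self.vxi = np.zeros(self.M)
        self.n_f: int | None = None

    def bind(self, n_f: int) -> None:
        self.n_f = int(n_f)

    @property
    def kT(self) -> float:  # internal units
        return KB * self.target_T / EUNIT

    @property
    def Q(self) -> np.ndarray:
        q = np.full(self.M, self.kT * self.tau**2)
        q[0] *= self.n_f
        return q

    def half_step(self, conf: Configuration, dt: float) -> None:
        """Advance the chain by dt/2 and scale particle velocities."""
        if self.n_f is None:
            raise RuntimeError("thermostat not bound: call bind(n_f) first")
        active = ~conf.frozen
        v = conf.velocities
        K2 = 2.0 * kinetic_energy(conf) / EUNIT  # Σ m v², internal
        Q = self.Q
        kT, nkt = self.kT, self.n_f * self.kT
        M = self.M
        scale = 1.0
        for w in _SY7:
            wdt = w * dt / 2.0
            wdt2, wdt4, wdt8 = wdt / 2.0, wdt / 4.0, wdt / 8.0
            G = (
                (Q[M - 2] * self.vxi[M - 2] ** 2 - kT) / Q[M - 1]
                if M > 1
                else (K2 - nkt) / Q[0]
            )
            self.vxi[M - 1] += wdt4 * G
            for j in range(M - 2, -1, -1):
                e = np.exp(-wdt8 * self.vxi[j + 1])
                self.vxi[j] *= e
                G = (K2 - nkt) / Q[0] if j == 0 else (
                    Q[j - 1] * self.vxi[j - 1] ** 2 - kT
                ) / Q[j]
                self.vxi[j] += wdt4 * G
                self.vxi[j] *= e
            s = np.exp(-wdt2 * self.vxi[0])
            scale *= s
            K2 *= s * s
            self.xi += wdt2 * self.vxi
            for j in range(M - 1):
                e = np.exp(-wdt8 * self.vxi[j + 1])
                self.vxi[j] *= e
                G = (K2 - nkt) / Q[0] if j == 0 else (
                    Q[j - 1] * self.vxi[j - 1] ** 2 - kT
                ) / Q[j]
                self.vxi[j] += wdt4 * G
                self.vxi[j] *= e
            G = (
                (Q[M - 2] * self.vxi[M - 2] ** 2 - kT) / Q[M - 1]
                if M > 1
                else (K2 - nkt) / Q[0]
            )
            self.vxi[M - 1] += wdt4 * G
        v[active] *= scale

    def energy(self) -> float:
        """Thermostat contribution to the conserved quantity, kJ/mol."""
        e = 0.5 * float(np.sum(self.Q * self.vxi**2))
        e += self.n_f * self.kT * self.xi[0]
        if self.M > 1:
            e += self.kT * float(np.sum(self.xi[1:]))
        return e * EUNIT


class Langevin:
    """Langevin (stochastic) thermostat applied as an O-step each MD step.

    ``gamma`` is the friction in 1/fs (default 0.002, i.e. a 500 fs
    velocity correlation time).  After the O-step the velocity component
    along a constrained coordinate is re-projected by the caller.
    """

    def __init__(self, target_T: float, gamma: float = 0.002, seed=None):
        self.target_T = float(target_T)
        self.gamma = float(gamma)
        self.rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )

    def o_step(self, conf: Configuration, dt: float) -> None:
        active = ~conf.frozen
        c1 = np.exp(-self.gamma * dt)
        kT_int = KB * self.target_T / EUNIT
        sigma = np.sqrt((1.0 - c1**2) * kT_int / conf.masses[active])
        conf.velocities[active] = (
            c1 * conf.velocities[active]
            + sigma[:, None] * self.rng.normal(size=(int(active.sum()), 3))
        )

    def energy(self) -> float:
        return 0.0


# ----------------------------------------------------------------------
# integration

def _project_velocity(
    conf: Configuration, spec: DynamicDistanceSpec
) -> None:
    """RATTLE velocity constraint: remove the component along ∇D."""
    grad = dynamic_distance_gradient(spec, conf.positions)
    minv_grad = grad / conf.masses[:, None]
    denom = float(np.sum(grad * minv_grad))
    if denom <= 0:
        return
    c = float(np.sum(grad * conf.velocities)) / denom
    conf.velocities -= c * minv_grad


def _solve_shake(
    spec: DynamicDistanceSpec,
    q_trial: np.ndarray,
    cvec: np.ndarray,
    target: float,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray]:
    """Damped Newton iteration for the scalar SHAKE multiplier."""
    lam = 0.0
    pos = q_trial
    g = dynamic_distance(spec, pos) - target
    for it in range(max_iter):
        if abs(g) <= tol:
            return lam, pos
        grad = dynamic_distance_gradient(spec, pos)
        slope = float(np.sum(grad * cvec))
        if slope == 0.0:
            break
        dlam = -g / slope
        for _ in range(25):
            new_lam = lam + dlam
            new_pos = q_trial + new_lam * cvec
            new_g = dynamic_distance(spec, new_pos) - target
            if abs(new_g) < abs(g) or abs(new_g) <= tol:
                lam, pos, g = new_lam, new_pos, new_g
                break
            dlam *= 0.5
        else:
            break
    raise ConstraintError(abs(g), max_iter)


def step_constrained(
    topo: ToyTopology,
    conf: Configuration,
    spec: DynamicDistanceSpec,
    cstate: ConstraintState,
    thermostat=None,
    dt: float = 0.5,
    forces: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """One RATTLE velocity-Verlet step at the current constraint target.

    Returns (potential energy, forces at the new positions, λ); the
    multiplier λ (kJ/mol/Å) is also appended to ``cstate.lambda_trace``.
    ``forces`` may carry the forces of the previous step to avoid one
    energy evaluation.
    """
    active = ~conf.frozen
    m = conf.masses[:, None]
    if forces is None:
        _, forces = energy_and_forces(topo, conf)

    if isinstance(thermostat, NoseHooverChain):
        thermostat.half_step(conf, dt)

    v = conf.velocities
    v[active] += 0.5 * dt * FCONV * forces[active] / m[active]
    grad_old = dynamic_distance_gradient(spec, conf.positions)
    q_trial = conf.positions + dt * v
    cvec = np.where(active[:, None], 0.5 * dt * dt * FCONV * grad_old / m, 0.0)
    lam, q_new = _solve_shake(
        spec, q_trial, cvec, cstate.target_D, cstate.tol, cstate.max_iter
    )
    conf.positions = q_new
    v[active] += (0.5 * dt * FCONV * lam) * grad_old[active] / m[active]

    e_pot, new_forces = energy_and_forces(topo, conf)
    v[active] += 0.5 * dt * FCONV * new_forces[active] / m[active]
    _project_velocity(conf, spec)

    if isinstance(thermostat, NoseHooverChain):
        thermostat.half_step(conf, dt)
    elif isinstance(thermostat, Langevin):
        thermostat.o_step(conf, dt)
        _project_velocity(conf, spec)

    cstate.lambda_trace.append(lam)
    return e_pot, new_forces, lam


def _step_free(topo, conf, thermostat, dt, forces):
    """Plain velocity-Verlet step (no constraint)."""
    active = ~conf.frozen
    m = conf.masses[:, None]
    if isinstance(thermostat, NoseHooverChain):
        thermostat.half_step(conf, dt)
    v = conf.velocities
    v[active] += 0.5 * dt * FCONV * forces[active] / m[active]
    conf.positions = conf.positions + dt * v
    e_pot, new_forces = energy_and_forces(topo, conf)
    v[active] += 0.5 * dt * FCONV * new_forces[active] / m[active]
    if isinstance(thermostat, NoseHooverChain):
        thermostat.half_step(conf, dt)
    elif isinstance(thermostat, Langevin):
        thermostat.o_step(conf, dt)
    return e_pot, new_forces


@dataclass
class MDResult:
    """Per-step traces and sampled frames of one MD run."""

    steps: np.ndarray
    temperature: np.ndarray
    e_pot: np.ndarray
    e_kin: np.ndarray
    conserved: np.ndarray
    d_target: np.ndarray
    d_measured: np.ndarray
    lambdas: np.ndarray
    frames: list
    frame_steps: list
    n_f: int
    aborted: bool = False

    @property
    def e_total(self) -> np.ndarray:
        return self.e_pot + self.e_kin


def _md_loop(
    topo: ToyTopology,
    conf: Configuration,
    steps: int,
    dt: float,
    thermostat,
    spec: DynamicDistanceSpec | None,
    target_fn,
    tol: float,
    max_iter: int,
    stride: int,
    record_frames: bool,
) -> MDResult:
    n_rec = steps
    rec = {
        k: np.empty(n_rec)
        for k in ("T", "epot", "ekin", "cons", "dtar", "dmeas", "lam")
    }
    frames, frame_steps = [], []
    remove_com = not isinstance(thermostat, Langevin)
    n_f = default_n_f(conf, spec is not None, remove_com)
    if isinstance(thermostat, NoseHooverChain):
        thermostat.bind(n_f)

    cstate = None
    if spec is not None:
        cstate = ConstraintState(spec, target_fn(0), tol, max_iter)
    _, forces = energy_and_forces(topo, conf)
    aborted = False
    for s in range(steps):
        try:
            if spec is not None:
                cstate.target_D = target_fn(s + 1)
                e_pot, forces, lam = step_constrained(
                    topo, conf, spec, cstate, thermostat, dt, forces
                )
            else:
                e_pot, forces = _step_free(topo, conf, thermostat, dt, forces)
                lam = np.nan
        except FloatingPointError:
            aborted = True
            for k in rec.values():
                k[s:] = np.nan
            break
        e_kin = kinetic_energy(conf)
        rec["T"][s] = 2.0 * e_kin / (n_f * KB)
        rec["epot"][s] = e_pot
        rec["ekin"][s] = e_kin
        extra = thermostat.energy() if thermostat is not None else 0.0
        rec["cons"][s] = e_pot + e_kin + extra
        rec["dtar"][s] = cstate.target_D if spec is not None else np.nan
        rec["dmeas"][s] = (
            dynamic_distance(spec, conf.positions) if spec is not None else np.nan
        )
        rec["lam"][s] = lam
        if record_frames and (s % stride == 0 or s == steps - 1):
            frames.append(conf.positions.copy())
            frame_steps.append(s + 1)
    return MDResult(
        steps=np.arange(1, steps + 1),
        temperature=rec["T"],
        e_pot=rec["epot"],
        e_kin=rec["ekin"],
        conserved=rec["cons"],
        d_target=rec["dtar"],
        d_measured=rec["dmeas"],
        lambdas=rec["lam"],
        frames=frames,
        frame_steps=frame_steps,
        n_f=n_f,
        aborted=aborted,
    )


def run_nvt(
    topo: ToyTopology,
    conf: Configuration,
    steps: int,
    dt: float = 0.5,
    thermostat=None,
    spec: DynamicDistanceSpec | None = None,
    target_D: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    stride: int = 50,
    record_frames: bool = True,
) -> MDResult:
    """NVT (or NVE when ``thermostat`` is None) run, optionally constrained.

    With a constraint spec, the dynamic distance is held at ``target_D``
    (defaulting to its current value) throughout.  Velocities must have
    been initialized beforehand (:func:`initialize_velocities`); a run
    that produces non-finite energies aborts, returning the traces up
    to the last good frame with ``aborted=True``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if spec is not None and target_D is None:
        target_D = dynamic_distance(spec, conf.positions)
    return _md_loop(
        topo, conf, steps, dt, thermostat, spec,
        (lambda s: target_D), tol, max_iter, stride, record_frames,
    )


def anneal(
    topo: ToyTopology,
    conf: Configuration,
    start_T: float,
    factor: float = 0.99,
    steps: int = 30000,
    rescale_interval: int = 100,
    dt: float = 0.5,
    thermostat: NoseHooverChain | Langevin | None = None,
    spec: DynamicDistanceSpec | None = None,
) -> tuple[Configuration, np.ndarray]:
    """Simulated annealing: thermostat target × ``factor`` per interval.

    Starting from ``start_T``, the target temperature is multiplied by
    the annealing factor every ``rescale_interval`` steps, reaching
    start_T·factor^(steps//interval).  Returns the relaxed
    configuration and the per-step target-temperature schedule.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("annealing factor must be in (0, 1]")
    if thermostat is None:
        thermostat = NoseHooverChain(start_T)
    schedule = start_T * factor ** (np.arange(steps) // rescale_interval)
    if steps == 0:
        return conf, schedule
    remove_com = not isinstance(thermostat, Langevin)
    n_f = default_n_f(conf, spec is not None, remove_com)
    if isinstance(thermostat, NoseHooverChain):
        thermostat.bind(n_f)
    cstate = None
    if spec is not None:
        cstate = ConstraintState(spec, dynamic_distance(spec, conf.positions))
    _, forces = energy_and_forces(topo, conf)
    for s in range(steps):
        thermostat.target_T = float(schedule[s])
        if spec is not None:
            _, forces, _ = step_constrained(
                topo, conf, spec, cstate, thermostat, dt, forces
            )
        else:
            _, forces = _step_free(topo, conf, thermostat, dt, forces)
    return conf, schedule


def zip_schedule(D_start: float, D_end: float, steps: int, step: int) -> float:
    """Linear ramp value at ``step`` (0..steps) from D_start to D_end."""
    if steps <= 0:
        raise ValueError("steps must be positive")
    return D_start + (D_end - D_start) * min(max(step, 0), steps) / steps


def zip_up(
    topo: ToyTopology,
    conf: Configuration,
    spec: DynamicDistanceSpec,
    D_start: float = 1.88,
    D_end: float = 1.56,
    steps: int = 10000,
    dt: float = 0.5,
    thermostat=None,
    seed: int | None = None,
    stride: int = 100,
) -> MDResult:
    """Zip up the hydrogen-bond structure by ramping D down.

    The constraint target moves linearly from ``D_start`` to ``D_end``
    over ``steps`` MD steps (the production protocol contracts the
    all-hydrogen-bond coordinate D_EQUI from 1.88 Å to 1.56 Å over
    10,000 steps); only the collective D is constrained, so individual
    hydrogen bonds remain free to trade distance.  The initial
    configuration must already be within 0.5 Å of ``D_start``.
    """
    if not (D_start >= D_end > 0):
        raise ValueError("require D_start >= D_end > 0")
    d0 = dynamic_distance(spec, conf.positions)
    if abs(d0 - D_start) > 0.5:
        raise ValueError(
            f"initial dynamic distance {d0:.3f} Å differs from the ramp "
            f"start {D_start:.3f} Å by more than 0.5 Å"
        )
    if thermostat is None:
        thermostat = NoseHooverChain(300.0)
    if not np.any(conf.velocities):
        initialize_velocities(
            conf, thermostat.target_T, np.random.default_rng(seed), spec
        )
    # bring D exactly onto the ramp start before stepping
    run_nvt(topo, conf, 1, dt, thermostat, spec, target_D=D_start,
            record_frames=False)
    return _md_loop(
        topo, conf, steps, dt, thermostat, spec,
        lambda s: zip_schedule(D_start, D_end, steps, s),
        1e-8, 50, stride, True,
    )
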