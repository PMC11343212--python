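"""Production force-protocol runs at the calibrated study conditions.

The paper-scale filament of 400 subunits is scaled down to 120 subunits
(~330 nm) for desk-scale simulation; the per-particle load of 5 pN on the
terminal five subunits (25 pN total, one-myosin scale) and the fixed first
five subunits are kept.  Time is internal simulation time (nominal masses),
with a per-phase duration long enough for the buckling instability to
develop and settle, chosen once on the compression protocol and used for
every condition.

Friction is set low (0.05 pN ns/nm) so that elastic recoil after force
release is underdamped — the regime in which transient tension produces
spiraling during recoil; the thermostat still equilibrates the filament on
the run timescale.
"""

from __future__ import annotations

from .calibration import ATP_CALIBRATED
from .dynamics import (
    ForceProtocol,
    IntegratorParams,
    Trajectory,
    protocol_summary,
    run_dynamics,
)
from .lattice import (
    LatticeParams,
    MechanicalParams,
    build_canonical_lattice,
    derive_topology,
)

__all__ = ["run_protocol", "PROTOCOL_DEFAULTS"]

PROTOCOL_DEFAULTS = {
    "n_subunits": 120,
    "dt": 0.002,
    # constant loads: moderate damping settles the buckled state; transient
    # loads: weak damping so elastic recoil after release is underdamped
    "friction_constant": 0.5,
    "friction_transient": 0.05,
    "apply_time": 100.0,
    "release_time": 150.0,
    "constant_time": 150.0,
    "per_particle_force": 5.0,
    "save_frames": 30,
}


def run_protocol(
    mode: str,
    sense: str,
    seed: int,
    mech: MechanicalParams | None = None,
    n_subunits: int | None = None,
    apply_time: float | None = None,
    release_time: float | None = None,
    per_particle_force: float | None = None,
) -> Trajectory:
    """Run one myosin-force protocol at the calibrated study conditions.

    ``mode``: "constant" or "apply_release" (transient); ``sense``:
    "tension" or "compression".  Returns the trajectory; summarize with
    :func:`actinmech.dynamics.protocol_summary`.
    """
    p = PROTOCOL_DEFAULTS
    mech = mech if mech is not None else ATP_CALIBRATED
    n = n_subunits or p["n_subunits"]
    dt = p["dt"]
    t_apply = apply_time if apply_time is not None else p["apply_time"]
    t_release = release_time if release_time is not None else p["release_time"]
    force = (
        per_particle_force if per_particle_force is not None else p["per_particle_force"]
    )
    config0 = build_canonical_lattice(LatticeParams(n_subunits=n))
    topo = derive_topology(config0)
    if mode == "constant":
        n_steps = int(p["constant_time"] / dt)
        friction = p["friction_constant"]
        protocol = ForceProtocol(mode="constant", sense=sense, per_particle_force=force)
    else:
        apply_steps = int(t_apply / dt)
        release_steps = int(t_release / dt)
        n_steps = apply_steps + release_steps
        friction = p["friction_transient"]
        protocol = ForceProtocol(
            mode="apply_release",
            sense=sense,
            per_particle_force=force,
            apply_steps=apply_steps,
            release_steps=release_steps,
        )
    integ = IntegratorParams(
        dt=dt,
        friction=friction,
        thermostat_on=True,
        seed=seed,
        n_steps=n_steps,
        save_every=max(1, n_steps // p["save_frames"]),
    )
    return run_dynamics(config0, topo, mech, protocol, integ)
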