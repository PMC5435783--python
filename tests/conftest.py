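import numpy as np
import pytest

from umiflow import (
    BoundaryCondition,
    DopplerFrame,
    FluidProps,
    Grid2D,
    SolverSettings,
    project_doppler,
    solve_steady,
    step,
)

BEAM_20 = np.array([np.sin(np.radians(20.0)), np.cos(np.radians(20.0))])


def straight_grid(nx=16, ny=30, dx=300e-6, dy=300e-6, band=13):
    lo = (ny - band) // 2
    return Grid2D(
        nx=nx, ny=ny, dx=dx, dy=dy,
        wall_lower_y=np.full(nx, lo), wall_upper_y=np.full(nx, lo + band - 1),
    )


@pytest.fixture(scope="session")
def small_grid():
    return straight_grid()


@pytest.fixture(scope="session")
def props():
    return FluidProps()


@pytest.fixture()
def settings():
    return SolverSettings()


def pulsatile_truth(grid, props, n_frames, profile=None, mean=0.25, amp=0.13,
                    period=0.933, dt=0.029075):
    """Small ground-truth run used as a twin by several test modules."""
    settings = SolverSettings(dt=dt)

    def u_of_t(t):
        return mean + amp * np.sin(2 * np.pi * t / period)

    kwargs = {} if profile is None else {"profile": profile}
    fields = [
        solve_steady(grid, BoundaryCondition(u_of_t(0.0), **kwargs), props,
                     settings, tol=1e-5)
    ]
    for k in range(1, n_frames):
        prev2 = fields[k - 2] if k >= 2 else None
        fields.append(
            step(fields[-1], BoundaryCondition(u_of_t(k * dt), **kwargs),
                 props, settings, grid, field_prev=prev2)
        )
        fields[-1].t = k * dt
    fields[0].t = 0.0
    return fields


def frames_from_fields(fields, grid, beam=BEAM_20, dt=0.029075):
    out = []
    for k, f in enumerate(fields):
        vc = project_doppler(f, beam, grid)
        out.append(
            DopplerFrame(vm=np.where(grid.fluid, vc, 0.0), beam=beam,
                         t=k * dt, valid=grid.fluid.copy())
        )
    return out


@pytest.fixture(scope="session")
def small_twin(small_grid, props):
    """8-frame noiseless twin on the small channel (skewed truth profile)."""
    from umiflow import skewed_profile

    fields = pulsatile_truth(small_grid, props, n_frames=8, profile=skewed_profile)
    return {"fields": fields, "frames": frames_from_fields(fields, small_grid)}
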