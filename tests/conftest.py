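"""Shared fixtures: default phantom and converged solves (session-scoped,
the conduction solves are the expensive part of the suite)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import emdasim as em
from emdasim.phantom import PatchSpec


@pytest.fixture(scope="session")
def default_phantom() -> em.LabelVolume:
    """Default synthetic pelvis at 2 mm spacing, seed 0 (no jitter)."""
    return em.generate_pelvis_phantom(em.PhantomParams())


@pytest.fixture(scope="session")
def default_solution(default_phantom):
    """Converged 20 mA conduction solve on the default phantom."""
    sol, system = em.solve_emda(default_phantom)
    return sol, system


@pytest.fixture(scope="session")
def posterior_patch_solution():
    """Same phantom but with the skin patches moved to the posterior wall."""
    params = dataclasses.replace(
        em.PhantomParams(),
        patches=PatchSpec(
            centers=((-45.0, -90.0, 30.0), (45.0, -90.0, 30.0)),
            normal=(0.0, -1.0, 0.0),
        ),
    )
    vol = em.generate_pelvis_phantom(params)
    sol, system = em.solve_emda(vol)
    return vol, sol


def make_slab(n_layers: int, sigma_layers, spacing_mm: float = 10.0,
              nx: int = 10, ny: int = 10):
    """1-D slab test problem: nx x ny cross-section, plate terminals at
    both z ends, per-layer conductivities in between.  Returns
    (cond, terminals) with the metal plates as source (z=0) / return."""
    from emdasim.phantom import SIGMA_ELECTRODE_S_PER_M

    nz = n_layers + 2
    grid = em.VoxelGrid(shape=(nx, ny, nz), spacing=(spacing_mm,) * 3)
    sigma = np.empty(grid.shape)
    for k in range(n_layers):
        sigma[:, :, k + 1] = sigma_layers[k % len(sigma_layers)] if np.ndim(
            sigma_layers) else sigma_layers
    sigma[:, :, 0] = sigma[:, :, -1] = SIGMA_ELECTRODE_S_PER_M
    cond = em.ConductivityVolume(grid=grid, sigma=sigma,
                                 excluded=np.zeros(grid.shape, dtype=bool))
    src = np.zeros(grid.shape, dtype=bool)
    src[:, :, 0] = True
    ret = np.zeros(grid.shape, dtype=bool)
    ret[:, :, -1] = True
    terms = em.TerminalSet(
        terminals=[em.Terminal("plate_lo", src, "source"),
                   em.Terminal("plate_hi", ret, "return")],
        injected_current_A=0.020,
    )
    return cond, terms


def make_concentric_spheres(spacing_mm: float, r_inner: float = 5.0,
                            r_outer: float = 50.0, sigma: float = 0.2):
    """Spherical conduction oracle: inner electrode sphere against an outer
    shell electrode in a homogeneous conductor; everything outside r_outer
    is excluded."""
    from emdasim.phantom import SIGMA_ELECTRODE_S_PER_M

    n = int(np.floor(2 * (r_outer + spacing_mm) / spacing_mm)) + 1
    origin = -((n - 1) / 2.0) * spacing_mm
    grid = em.VoxelGrid(shape=(n, n, n), spacing=(spacing_mm,) * 3,
                        origin=(origin,) * 3)
    x, y, z = grid.coordinate_arrays()
    r = np.sqrt(x**2 + y**2 + z**2)
    inside = r <= r_outer
    inner = r <= r_inner
    outer_shell = inside & (r > r_outer - 1.5 * spacing_mm)
    sig = np.full(grid.shape, sigma)
    sig[inner] = SIGMA_ELECTRODE_S_PER_M
    sig[outer_shell] = SIGMA_ELECTRODE_S_PER_M
    cond = em.ConductivityVolume(grid=grid, sigma=sig, excluded=~inside)
    terms = em.TerminalSet(
        terminals=[em.Terminal("inner", inner, "source"),
                   em.Terminal("outer", outer_shell, "return")],
        injected_current_A=0.020,
    )
    return cond, terms, r


import functools


@functools.lru_cache(maxsize=None)
def sphere_profile_error(spacing_mm: float) -> float:
    """Max relative deviation of shell-averaged V from the analytic 1/r
    profile, as a fraction of the compared potential span."""
    cond, terms, r = make_concentric_spheres(spacing_mm)
    system = em.assemble_system(cond, terms)
    sol = em.solve_potential(system, cond, terms, tol=1e-8)
    sigma = 0.2
    I = terms.injected_current_A
    r_lo = 5.0 + 2.0 * spacing_mm  # exclude the singular electrode neighborhood
    r_hi = 45.0
    shells = np.arange(r_lo, r_hi, spacing_mm)
    v_num, v_ana = [], []
    for r0 in shells:
        m = (r >= r0) & (r < r0 + spacing_mm) & sol.valid
        v_num.append(np.nanmean(sol.V[m]))
        rm = np.mean(r[m]) * 1e-3  # mm -> m
        v_ana.append(I / (4 * np.pi * sigma * rm))
    v_num, v_ana = np.asarray(v_num), np.asarray(v_ana)
    v_ana = v_ana - v_ana.mean() + v_num.mean()  # analytic offset is free
    span = v_ana.max() - v_ana.min()
    return float(np.max(np.abs(v_num - v_ana)) / span)
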