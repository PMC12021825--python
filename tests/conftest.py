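"""Shared fixtures: phantoms are expensive, so the large ones used by the
parameter-recovery checks are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from axonmorph import (PhantomSpec, Uniform, generate_phantom, measure_mask,
                       preset_spec)


def _run(spec):
    mask, labels, truth = generate_phantom(spec)
    metrics, instances, qc, dens = measure_mask(mask)
    return {"mask": mask, "labels": labels, "truth": truth,
            "metrics": metrics, "instances": instances, "qc": qc,
            "density": dens, "spec": spec}


@pytest.fixture(scope="session")
def wt_area_phantom():
    """Area-mode phantom, wild-type axon/myelin-area presets, n=1000."""
    return _run(preset_spec("wild_type", "area", n_axons=1000, seed=101))


@pytest.fixture(scope="session")
def mut_area_phantom():
    """Area-mode phantom, mutant axon/myelin-area presets, n=1000."""
    return _run(preset_spec("mutant", "area", n_axons=1000, seed=102))


@pytest.fixture(scope="session")
def wt_geom_phantom():
    """Geometry-mode phantom, wild-type diameter/thickness presets, n=1000."""
    return _run(preset_spec("wild_type", "geometry", n_axons=1000, seed=103))


@pytest.fixture(scope="session")
def mut_geom_phantom():
    """Geometry-mode phantom, mutant thickness preset, n=1000."""
    return _run(preset_spec("mutant", "geometry", n_axons=1000, seed=104))


@pytest.fixture(scope="session")
def uniform_thickness_phantom():
    """Geometry-mode phantom with wall thickness uniform over 0.10-0.22 μm,
    220 sheaths at 8 nm pitch — the automated-vs-manual validation layout."""
    spec = preset_spec("wild_type", "geometry", n_axons=220, seed=105)
    dists = dict(spec.distributions, thickness=Uniform(0.10, 0.22))
    spec = PhantomSpec(mode="geometry", n_axons=220, distributions=dists,
                       pixel_size=8.0, seed=105)
    return _run(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Small geometry-mode phantom for structural/unit checks (16 nm pitch)."""
    return _run(preset_spec("wild_type", "geometry", n_axons=40, seed=7,
                            pixel_size=16.0))


def draw_annulus(canvas, cr, cc, r_in, r_out, lumen=True):
    """Paint a circular annulus (class 2) with optional class-1 lumen."""
    yy, xx = np.mgrid[: canvas.shape[0], : canvas.shape[1]]
    rad = np.hypot(yy - cr, xx - cc)
    canvas[(rad > r_in) & (rad <= r_out)] = 2
    if lumen:
        canvas[rad <= r_in] = 1
    return canvas
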