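"""Shared fixtures: reduced-scale simulation runs reused across tests.

The heavy fixtures are session-scoped so the full 0.5 mm validation run
and the 1 mm M-mode run are simulated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import pulsart as pa
from pulsart.pipeline import build_waveform, substream_seed

SESSION_SEED = 0


@pytest.fixture(scope="session")
def run05():
    """Full reduced-scale 0.5 mm peak-to-peak validation run, both
    estimators, accumulated and evaluated."""
    cfg = pa.desk_scale_config(0.5, seed=SESSION_SEED)
    result = pa.run_pipeline(cfg)
    return cfg, result


@pytest.fixture(scope="session")
def run1mm():
    """1 mm peak-to-peak cycle scanned on five lines around the midline
    (for M-mode wall tracking and inter-extreme-frame echo shifts)."""
    cfg = pa.desk_scale_config(1.0, seed=SESSION_SEED, density_multiplier=0.25)
    smap = pa.generate_scatterers(
        cfg.geometry,
        cfg.scattering,
        cfg.transducer,
        cfg.density_per_cell,
        seed=substream_seed(SESSION_SEED, "phantom"),
    )
    waveform = build_waveform(cfg)
    dyn = pa.animate(smap, waveform, cfg.slopes)
    seq = pa.render_sequence(
        dyn, cfg.transducer, cfg.scan, line_x_mm=np.linspace(-1.0, 1.0, 5)
    )
    return {"config": cfg, "static": smap, "waveform": waveform, "dynamic": dyn, "sequence": seq}


@pytest.fixture(scope="session")
def ambiguity_fractions(run1mm):
    """1DCC invalid fraction at the wall bands for the three
    peak-to-peak levels, midline line only."""
    cfg = run1mm["config"]
    smap = run1mm["static"]
    fracs = {}
    for pp in (0.5, 0.75, 1.0):
        wf = build_waveform(
            pa.desk_scale_config(pp, seed=SESSION_SEED, density_multiplier=0.25)
        )
        dyn = pa.animate(smap, wf, cfg.slopes)
        seq = pa.render_sequence(
            dyn, cfg.transducer, cfg.scan, line_x_mm=np.array([0.0])
        )
        field = pa.cc1d_interframe(seq)
        fracs[pp] = pa.invalid_fraction(field)
    return fracs


@pytest.fixture()
def default_geometry():
    return pa.ArteryGeometry()


@pytest.fixture()
def default_transducer():
    return pa.TransducerConfig()


@pytest.fixture()
def slopes():
    return pa.SlopeParams()
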