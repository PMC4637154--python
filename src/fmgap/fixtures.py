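"""Deterministic reference-output generation for regression tests.

``make_fixtures`` regenerates small, coarse-grid reference runs (fixed-step
integration, so byte-stable across platforms at fixed parameters) together
with a hash of every shipped model parameter.  Regression tests compare
fresh runs against the checked-in files; a parameter change flips the hash
and fails the comparison until the fixtures are regenerated deliberately.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config_io import parameter_hash, read_table, write_table
from .coupling import CouplingConfig, CoupledSystem
from .gapjunction import steady_state_curve
from .membrane import StimulusProtocol

__all__ = ["make_fixtures", "check_fixtures", "FIXTURE_SPECS"]

_STIM = StimulusProtocol(amplitude=6000.0, duration=1.0, n_beats=1, onset=10.0)


def _uncoupled_frame() -> pd.DataFrame:
    cfg = CouplingConfig(N=0, gj_model="static", G_j_max=1.0, stimulus=_STIM)
    tr = CoupledSystem(cfg).simulate(300.0, output_dt=1.0, method="fixed",
                                     dt=0.02)
    return tr.to_frame().round(6)

def _pair_frame() -> pd.DataFrame:
    cfg = CouplingConfig(N=1, fibroblast="active", gj_model="Cx43",
                         G_j_max=3.0, stimulus=_STIM)
    tr = CoupledSystem(cfg).simulate(300.0, output_dt=2.0, method="fixed",
                                     dt=0.02)
    return tr.to_frame().round(6)

def _curves_frame() -> pd.DataFrame:
    grid = np.arange(-100.0, 101.0, 5.0)
    cols = {"V_j": grid}
    for pheno in ("Cx43", "Cx45", "Cx43/Cx45"):
        cols[pheno.replace("/", "_")] = steady_state_curve(pheno, grid).G_norm
    return pd.DataFrame(cols).round(9)


FIXTURE_SPECS = {
    "uncoupled_myocyte.csv": _uncoupled_frame,
    "pair_cx43_coarse.csv": _pair_frame,
    "gj_curves_coarse.csv": _curves_frame,
}


def make_fixtures(outdir) -> dict:
    """(Re)generate the bundled reference outputs under ``outdir``.

    No-op when the files already match the current parameter hash.  Returns
    a mapping of file name -> "written" | "unchanged".
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_path = outdir / "fixture_meta.json"
    current = parameter_hash()
    status = {}
    stale = True
    if meta_path.exists():
        stale = json.loads(meta_path.read_text()).get("hash") != current
    for name, builder in FIXTURE_SPECS.items():
        path = outdir / name
        if path.exists() and not stale:
            status[name] = "unchanged"
            continue
        write_table(builder(), path, {"fixture": name})
        status[name] = "written"
    meta_path.write_text(json.dumps({"hash": current}, indent=1))
    return status


def check_fixtures(outdir, rtol: float = 1e-9) -> None:
    """Verify the checked-in fixtures against freshly computed runs.

    Raises AssertionError with a regeneration instruction when the
    parameter hash or any value diverges.
    """
    outdir = Path(outdir)
    meta_path = outdir / "fixture_meta.json"
    current = parameter_hash()
    stored = json.loads(meta_path.read_text()).get("hash")
    if stored != current:
        raise AssertionError(
            f"model parameters changed (hash {stored} -> {current}); "
            f"re-bless the fixtures with fmgap.fixtures.make_fixtures({str(outdir)!r})"
        )
    for name, builder in FIXTURE_SPECS.items():
        ref = read_table(outdir / name)
        new = builder()
        if not np.allclose(ref.to_numpy(), new.to_numpy(), rtol=rtol,
                           atol=1e-9, equal_nan=True):
            raise AssertionError(
                f"fixture {name} diverges from a fresh run; regenerate with "
                f"make_fixtures({str(outdir)!r}) if the change is intended"
            )
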