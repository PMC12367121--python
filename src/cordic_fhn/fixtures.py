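"""Small seeded reference artifacts used by the test suite and docs.

Everything here is generated programmatically (no stored data files): a
pair of short single-neuron trajectories per model and backend, a
20-neuron mini-network raster pair, and a reduced cube-error sweep.
"""

from __future__ import annotations

from pathlib import Path

from .cordic import cube_error_sweep
from .io import write_csv
from .models import DriveSpec, FHNParams, simulate_discrete
from .network import NetworkConfig, build_network, simulate_network

__all__ = ["make_fixtures"]


def make_fixtures(seed: int = 42, outdir: str | Path | None = None) -> dict:
    """Generate the fixture bundle; optionally write it under ``outdir``.

    Returns a dict with trajectories (``traj/<model>/<backend>``), the
    mini-network rasters (``raster/<model>``) and the reduced iteration
    sweep (``cube_sweep``).
    """
    params = FHNParams()
    drive = DriveSpec.constant(0.5)
    bundle: dict = {"seed": seed}
    for model in ("fhn", "cordic"):
        for backend in ("real", "fixed"):
            traj = simulate_discrete(model, params, drive, n_steps=6400, backend=backend)
            bundle[f"traj/{model}/{backend}"] = traj
    cfg = NetworkConfig(n_neurons=20, degree=5, duration=300.0, crop=250.0, seed=seed)
    net = build_network(cfg)
    for model in ("fhn", "cordic"):
        bundle[f"raster/{model}"] = simulate_network(net, model)
    bundle["network"] = net
    bundle["cube_sweep"] = cube_error_sweep([10, 12, 14, 16, 18, 20], grid_step=1.0 / 50.0)
    if outdir is not None:
        outdir = Path(outdir)
        for key, traj in ((k, v) for k, v in bundle.items() if k.startswith("traj/")):
            name = key.replace("/", "_")
            write_csv(outdir / f"{name}.csv", traj.to_frame(), config=traj.meta)
        for model in ("fhn", "cordic"):
            raster = bundle[f"raster/{model}"]
            (outdir / f"raster_{model}.json").parent.mkdir(parents=True, exist_ok=True)
            (outdir / f"raster_{model}.json").write_text(raster.to_json())
        write_csv(outdir / "cube_sweep.csv", bundle["cube_sweep"])
    return bundle
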