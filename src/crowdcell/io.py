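"""Config file loading and run-output writing.

The YAML schema mirrors the dataclasses: top-level simulation settings, a
``species`` list and a ``reactions`` list; the geometry is either an empty
cell (``cell_radius``), a CSV file (``geometry_file``) or generated in
place (``geometry: {cell_radius, n_cylinders, cyl_length, cyl_radius,
n_spheres, sph_radius, seed, density_multiplier}``).
"""

from __future__ import annotations

import json
import pathlib

import yaml

from .dynamics import SpeciesSpec
from .engine import ObservableSeries, SimulationConfig
from .geometry import CellGeometry, generate_geometry
from .reactions import ReactionSpec


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "geometry_file" in raw:
        geom = CellGeometry.load_csv(raw.pop("geometry_file"))
    elif "geometry" in raw:
        geom = generate_geometry(**raw.pop("geometry"))
    else:
        geom = CellGeometry(raw.pop("cell_radius"))
    def _floats(d, keys):
        # YAML 1.1 reads exponents without a sign ("7.57e5") as strings
        for k in keys:
            if d.get(k) is not None:
                d[k] = float(d[k])
        return d

    species = [SpeciesSpec(**_floats(dict(s), ("radius", "D0",
                                               "shell_thickness")))
               for s in raw.pop("species")]
    reactions = []
    for r in raw.pop("reactions", []):
        r = _floats(dict(r), ("k_macro", "molecules_per_s",
                              "shell_thickness", "capture_layer",
                              "kD_reference"))
        r["educts"] = tuple(r.get("educts", ()))
        r["products"] = tuple(r.get("products", ()))
        reactions.append(ReactionSpec(**r))
    _floats(raw, ("dt", "t_end", "observation_interval"))
    return SimulationConfig(geometry=geom, species=species,
                            reactions=reactions, **raw)


def run_manifest(series: ObservableSeries) -> dict:
    """Provenance record: versions, seeds, derived kernel parameters."""
    import numba
    import numpy

    from . import __version__

    config = series.config
    manifest = {
        "crowdcell_version": __version__,
        "numpy_version": numpy.__version__,
        "numba_version": numba.__version__,
        "step_order": ["diffusion", "adsorption/dissociation", "bimolecular",
                       "unimolecular", "zero_order", "membrane_export",
                       "observation"],
    }
    if config is not None:
        manifest.update({
            "dt": config.dt, "t_end": config.t_end, "seed": config.seed,
            "observation_interval": config.observation_interval,
            "species": [s.name for s in config.species],
            "bimolecular_kernels": {
                name: {"R_crit_um": k.R_crit, "k_D": k.k_D,
                       "k_micro": k.k_micro, "P_react": k.P_react}
                for name, k in config.bimolecular_kernels().items()},
        })
    return manifest


def write_run_outputs(series: ObservableSeries, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series.counts_frame().to_csv(out / "counts.csv")
    series.events_frame().to_csv(out / "events.csv")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest(series), fh, indent=2)
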