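"""File formats: capture/effort/track CSVs, GeoJSON masks, ESRI ASCII grids.

All tabular formats are plain CSV with km units.  GeoJSON polygons are
read and written through shapely; the ESRI ASCII grid reader/writer
covers the on/off habitat rasters and density-surface exports (the format
is a six-line header plus a whitespace array).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .model import CaptureData
from .state_space import EffortArray, TrapGrid, distance_matrix

__all__ = [
    "read_tracks_csv", "write_tracks_csv",
    "read_playbacks_csv", "write_playbacks_csv",
    "read_capture_csv", "write_capture_csv",
    "write_effort_csv", "read_effort_csv",
    "read_geojson_polygons", "write_geojson_polygons",
    "read_ascii_grid", "write_ascii_grid",
    "write_bundle", "read_bundle_inputs",
]

_SEX_CODE = {"F": 0, "M": 1, "U": -1}
_SEX_NAME = {0: "F", 1: "M", -1: "U"}


def read_tracks_csv(path):
    """Tracks as [(vertices, occasion), ...] from occasion,segment_id,x_km,y_km."""
    df = pd.read_csv(path, float_precision="round_trip")
    tracks = []
    for (occ, _seg), g in df.groupby(["occasion", "segment_id"], sort=True):
        tracks.append((g[["x_km", "y_km"]].to_numpy(float), int(occ)))
    return tracks


def write_tracks_csv(tracks, path) -> None:
    rows = []
    for seg_id, (vertices, occ) in enumerate(tracks):
        for x, y in np.asarray(vertices):
            rows.append((occ, seg_id, repr(float(x)), repr(float(y))))
    pd.DataFrame(rows, columns=["occasion", "segment_id", "x_km", "y_km"]) \
        .to_csv(path, index=False)


def read_playbacks_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    return [(np.array([r.x_km, r.y_km]), int(r.occasion)) for r in df.itertuples()]


def write_playbacks_csv(playbacks, path) -> None:
    rows = [(occ, repr(float(p[0])), repr(float(p[1]))) for p, occ in playbacks]
    pd.DataFrame(rows, columns=["occasion", "x_km", "y_km"]).to_csv(path, index=False)


def write_capture_csv(data: CaptureData, traps: TrapGrid, path) -> None:
    """Long-format capture history: individual_id, trap_id, occasion, sex."""
    yi, yj, yk = np.nonzero(data.y)
    pd.DataFrame({
        "individual_id": [f"ind{int(i)}" for i in yi],
        "trap_id": traps.cell_ids[yj],
        "occasion": yk + 1,
        "sex": [_SEX_NAME[int(data.sex_obs[i])] for i in yi],
    }).to_csv(path, index=False)


def read_capture_csv(path, traps: TrapGrid, effort: EffortArray,
                     state_space=None, dist=None) -> CaptureData:
    """Build a CaptureData from a capture-history CSV.

    Individuals are ordered by first appearance in the file.  ``dist``
    (pixel x trap distances) is computed from ``state_space`` when not
    given directly.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    trap_index = {tid: j for j, tid in enumerate(traps.cell_ids)}
    ids = list(dict.fromkeys(df["individual_id"]))
    ind_index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    J, K = effort.search_km.shape
    y = np.zeros((n, J, K), dtype=np.uint8)
    sex_obs = np.full(n, -1, dtype=np.int8)
    for r in df.itertuples():
        if r.trap_id not in trap_index:
            raise ValueError(f"capture references unknown trap {r.trap_id}")
        if not (1 <= r.occasion <= K):
            raise ValueError(f"occasion {r.occasion} outside [1, {K}]")
        i = ind_index[r.individual_id]
        y[i, trap_index[r.trap_id], r.occasion - 1] = 1
        if hasattr(r, "sex") and isinstance(r.sex, str):
            sex_obs[i] = _SEX_CODE.get(r.sex.upper(), -1)
    if dist is None:
        if state_space is None:
            raise ValueError("need state_space or dist to build CaptureData")
        dist = distance_matrix(state_space, traps)
    data = CaptureData(y=y, sex_obs=sex_obs, effort=effort, dist=dist,
                       trap_grid=traps)
    data.validate()
    return data


def write_effort_csv(effort: EffortArray, traps: TrapGrid, path) -> None:
    """Long-format effort: trap_id, occasion, search_km, playback.

    Only active cell-occasions are written; trap coordinates travel in the
    companion trap-grid CSV.
    """
    df = effort.to_dataframe(traps)
    df["search_km"] = [repr(float(v)) for v in df["search_km"]]
    df.to_csv(path, index=False)


def write_trap_grid_csv(traps: TrapGrid, path) -> None:
    pd.DataFrame({
        "trap_id": traps.cell_ids,
        "x_km": [repr(float(v)) for v in traps.cell_centroids[:, 0]],
        "y_km": [repr(float(v)) for v in traps.cell_centroids[:, 1]],
        "ix": traps.cell_ij[:, 0],
        "iy": traps.cell_ij[:, 1],
    }).to_csv(path, index=False)


def read_trap_grid_csv(path, cell_km2: float = 1.0) -> TrapGrid:
    tg = pd.read_csv(path, float_precision="round_trip")
    return TrapGrid(
        cell_centroids=tg[["x_km", "y_km"]].to_numpy(float),
        cell_area=cell_km2,
        cell_ids=tg["trap_id"].to_numpy(object),
        cell_ij=tg[["ix", "iy"]].to_numpy(np.int64),
    )


def read_effort_csv(effort_path, trap_grid_path, n_occasions: int,
                    cell_km2: float = 1.0):
    """(TrapGrid, EffortArray) from the long-format effort + trap CSVs."""
    traps = read_trap_grid_csv(trap_grid_path, cell_km2)
    df = pd.read_csv(effort_path, float_precision="round_trip")
    J = traps.n_traps
    search = np.zeros((J, n_occasions))
    playback = np.zeros((J, n_occasions), dtype=np.int8)
    trap_index = {tid: j for j, tid in enumerate(traps.cell_ids)}
    for r in df.itertuples():
        j = trap_index[r.trap_id]
        search[j, r.occasion - 1] = float(r.search_km)
        playback[j, r.occasion - 1] = int(r.playback)
    return traps, EffortArray(search_km=search, playback=playback,
                              n_occasions=n_occasions)


def read_geojson_polygons(path):
    """List of shapely polygons from a GeoJSON file (holes allowed)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [gj["geometry"]]
    else:
        geoms = [gj]
    return [shape(g) for g in geoms]


def write_geojson_polygons(polygons, path) -> None:
    features = [{"type": "Feature", "properties": {}, "geometry": mapping(p)}
                for p in polygons]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ascii_grid(path):
    """(array, xllcorner, yllcorner, cellsize) from an ESRI ASCII grid.

    Row 0 of the returned array is the top (northern) row, as stored.
    """
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:])
    grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    if "nodata_value" in header:
        grid = np.where(grid == header["nodata_value"], np.nan, grid)
    return grid, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_ascii_grid(grid, xll: float, yll: float, cellsize: float, path,
                     nodata: float = -9999.0) -> None:
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_bundle(bundle, out_dir: Path) -> None:
    """Write a synthetic survey as the package's standard input files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tracks_csv(bundle.tracks, out_dir / "tracks.csv")
    write_playbacks_csv(bundle.playbacks, out_dir / "playbacks.csv")
    write_effort_csv(bundle.effort, bundle.trap_grid, out_dir / "effort.csv")
    write_trap_grid_csv(bundle.trap_grid, out_dir / "trap_grid.csv")
    write_capture_csv(bundle.capture, bundle.trap_grid, out_dir / "capture.csv")
    write_geojson_polygons([bundle.config.survey_polygon()],
                           out_dir / "survey_area.geojson")
    (out_dir / "truth.json").write_text(bundle.truth.to_json())
    cfg = {
        "seed": bundle.config.seed,
        "survey_area_km2": bundle.config.survey_area_km2,
        "n_occasions": bundle.config.n_occasions,
        "km_per_occasion": bundle.config.km_per_occasion,
        "leg_km": bundle.config.leg_km,
        "patrol_radius_km": bundle.config.patrol_radius_km,
        "n_playbacks": bundle.config.n_playbacks,
        "buffer_km": bundle.config.buffer_km,
        "pixel_area_km2": bundle.config.pixel_area_km2,
        "cell_km2": bundle.config.cell_km2,
        "M": bundle.config.M,
        "truth": {k: v for k, v in vars(bundle.config.truth).items()},
        "model": {
            "lambda0_sex_specific": bundle.config.spec.lambda0_sex_specific,
            "sigma_sex_specific": bundle.config.spec.sigma_sex_specific,
            "theta": bundle.config.spec.theta,
            "M": bundle.config.spec.M,
            "include_playback": bundle.config.spec.include_playback,
        },
    }
    (out_dir / "simulation_config.json").write_text(json.dumps(cfg, indent=1))


def read_bundle_inputs(in_dir):
    """Reload the input files written by :func:`write_bundle`.

    Returns ``(config_dict, tracks, playbacks, traps, effort, capture_df)``;
    rebuilding model-ready arrays additionally needs the state-space (see
    the fit pipeline in :mod:`lionscr.cli`).
    """
    in_dir = Path(in_dir)
    cfg = json.loads((in_dir / "simulation_config.json").read_text())
    tracks = read_tracks_csv(in_dir / "tracks.csv")
    playbacks = read_playbacks_csv(in_dir / "playbacks.csv")
    traps, effort = read_effort_csv(in_dir / "effort.csv",
                                    in_dir / "trap_grid.csv",
                                    n_occasions=cfg["n_occasions"],
                                    cell_km2=cfg["cell_km2"])
    capture_df = pd.read_csv(in_dir / "capture.csv")
    return cfg, tracks, playbacks, traps, effort, capture_df


# ---------------------------------------------------------------------------
# State-space and posterior-sample persistence (for the CLI pipeline)


def state_space_to_ascii(state_space, path) -> None:
    """Persist the lattice as an ASCII grid: 1 habitat, 0 masked, nodata outside."""
    ny, nx = state_space.shape
    grid = np.full((ny, nx), np.nan)
    ij = state_space.ij
    grid[ij[:, 1], ij[:, 0]] = state_space.habitat.astype(float)
    # ASCII grids store the northern row first
    write_ascii_grid(grid[::-1], state_space.origin[0], state_space.origin[1],
                     state_space.spacing, path)


def state_space_from_ascii(path, buffer_km: float):
    from .state_space import StateSpace

    grid, xll, yll, cellsize = read_ascii_grid(path)
    grid = grid[::-1]                      # back to southern row first
    iy, ix = np.nonzero(~np.isnan(grid))
    centroids = np.column_stack([xll + (ix + 0.5) * cellsize,
                                 yll + (iy + 0.5) * cellsize])
    order = np.lexsort((ix, iy))
    ix, iy = ix[order], iy[order]
    centroids = centroids[order]
    return StateSpace(
        centroids=centroids,
        pixel_area=cellsize * cellsize,
        habitat=grid[iy, ix] == 1,
        buffer_km=buffer_km,
        origin=(xll, yll),
        shape=grid.shape,
        ij=np.column_stack([ix, iy]),
    )


def save_samples(samples, out_dir) -> None:
    """One CSV per chain plus a binary sidecar for the latent draws."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c in range(samples.n_chains):
        samples.to_dataframe(c).to_csv(out_dir / f"chain{c}.csv", index=False,
                                       float_format="%.17g")
    np.savez_compressed(
        out_dir / "latents.npz",
        z=samples.latent_z, s=samples.latent_s, sex=samples.latent_sex,
        iters=samples.latent_iters,
    )
    meta = {
        "names": samples.names,
        "n_chains": samples.n_chains,
        "acceptance": {k: v.tolist() for k, v in samples.acceptance.items()},
        "config": {
            "seed": samples.config.seed,
            "n_chains": samples.config.n_chains,
            "n_iter": samples.config.n_iter,
            "burn_in": samples.config.burn_in,
            "thin": samples.config.thin,
            "latent_stride": samples.config.latent_stride,
        },
        "spec": {
            "lambda0_sex_specific": samples.spec.lambda0_sex_specific,
            "sigma_sex_specific": samples.spec.sigma_sex_specific,
            "theta": samples.spec.theta,
            "M": samples.spec.M,
            "include_playback": samples.spec.include_playback,
        },
    }
    (out_dir / "samples_meta.json").write_text(json.dumps(meta, indent=1))


def load_samples(in_dir):
    from .mcmc import ChainConfig, PosteriorSamples
    from .model import ModelSpec

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "samples_meta.json").read_text())
    spec = ModelSpec(**meta["spec"])
    config = ChainConfig(**meta["config"])
    frames = [pd.read_csv(in_dir / f"chain{c}.csv", float_precision="round_trip")
              for c in range(meta["n_chains"])]
    draws = {name: np.stack([f[name].to_numpy() for f in frames])
             for name in meta["names"]}
    lat = np.load(in_dir / "latents.npz")
    return PosteriorSamples(
        spec=spec, config=config, names=meta["names"], draws=draws,
        n_super=np.stack([f["n_super"].to_numpy() for f in frames]),
        loglik=np.stack([f["loglik"].to_numpy() for f in frames]),
        latent_z=lat["z"], latent_s=lat["s"], latent_sex=lat["sex"],
        latent_iters=lat["iters"],
        acceptance={k: np.array(v) for k, v in meta["acceptance"].items()},
    )
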