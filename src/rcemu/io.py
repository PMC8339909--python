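"""Readers and writers for every on-disk artifact.

Conventions: CSV for tabular data (human-diffable; numeric columns at full
repr precision), JSON for metadata, NumPy ``.npz`` containers for matrices.
Every artifact carries a schema version and seed provenance — CSV files via
leading ``#`` comment lines, binary containers via a JSON metadata entry.
Version mismatches raise; truncated files raise parse errors rather than
returning silently corrupted data.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CurveObservations, ERPBracket, MCMCResult
from .curves import CurveBasis
from .emulator import RCE
from .gp import GaussianProcess, GPHyperparams
from .params import PARAM_NAMES

SCHEMA_VERSION = 1


class ArtifactError(RuntimeError):
    """Unreadable, truncated, or wrong-version artifact."""


def _header(kind: str, seed) -> str:
    return f"# rcemu-artifact: {kind} v{SCHEMA_VERSION}\n# seed: {seed}\n"


def _check_header(path: Path, kind: str):
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# rcemu-artifact:"):
        raise ArtifactError(f"{path}: missing artifact header (not a {kind} file?)")
    fields = first.split(":", 1)[1].strip().split()
    got_kind, got_ver = fields[0], fields[1]
    if got_kind != kind:
        raise ArtifactError(f"{path}: artifact kind {got_kind!r}, expected {kind!r}")
    if got_ver != f"v{SCHEMA_VERSION}":
        raise ArtifactError(f"{path}: schema version {got_ver} != v{SCHEMA_VERSION}")


def _write_csv(df: pd.DataFrame, path: Path, kind: str, seed):
    with open(path, "w") as fh:
        fh.write(_header(kind, seed))
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path, kind: str, expected_cols=None) -> pd.DataFrame:
    path = Path(path)
    _check_header(path, kind)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as err:
        raise ArtifactError(f"{path}: parse error: {err}") from err
    if expected_cols is not None and list(df.columns) != list(expected_cols):
        raise ArtifactError(f"{path}: columns {list(df.columns)} != {list(expected_cols)}")
    return df


# -- designs ---------------------------------------------------------------

def write_design(design: np.ndarray, path, seed=None) -> None:
    df = pd.DataFrame(np.asarray(design, float), columns=list(PARAM_NAMES))
    _write_csv(df, Path(path), "design", seed)


def read_design(path) -> np.ndarray:
    df = _read_csv(Path(path), "design", expected_cols=PARAM_NAMES)
    return df.to_numpy(dtype=float)


# -- curve matrices --------------------------------------------------------

def write_curves(curves: np.ndarray, grid: np.ndarray, path, seed=None) -> None:
    cols = [f"s_{g:g}" for g in grid]
    df = pd.DataFrame(np.asarray(curves, float), columns=cols)
    _write_csv(df, Path(path), "curves", seed)


def read_curves(path):
    """Returns (curves, grid)."""
    df = _read_csv(Path(path), "curves")
    try:
        grid = np.array([float(c[2:]) for c in df.columns])
    except ValueError as err:
        raise ArtifactError(f"{path}: malformed grid columns") from err
    return df.to_numpy(dtype=float), grid


# -- restitution run -------------------------------------------------------

def write_run(run, path_csv, path_json, seed=None) -> None:
    df = pd.DataFrame({"s2_ms": run.s2, "cv_m_per_s": run.cv, "apd_ms": run.apd})
    _write_csv(df, Path(path_csv), "run", seed)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "params": dict(zip(PARAM_NAMES, run.params.as_array().tolist())),
        "s1_ms": run.s1,
        "erp_ms": int(run.erp),
        "flags": {"n_trials": len(run.trial_log)},
    }
    with open(path_json, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


# -- PCA basis -------------------------------------------------------------

def write_basis(basis: CurveBasis, path) -> None:
    np.savez(path,
             meta=json.dumps({"schema_version": SCHEMA_VERSION, "n_train": basis.n_train}),
             grid=basis.grid, mean=basis.mean, components=basis.components,
             explained_variance_ratio=basis.explained_variance_ratio)


def read_basis(path) -> CurveBasis:
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["schema_version"] != SCHEMA_VERSION:
                raise ArtifactError(f"{path}: schema version {meta['schema_version']}")
            return CurveBasis(grid=z["grid"], mean=z["mean"], components=z["components"],
                              explained_variance_ratio=z["explained_variance_ratio"],
                              n_train=int(meta["n_train"]))
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as err:
        raise ArtifactError(f"{path}: unreadable basis: {err}") from err


# -- GP models and RCEs ----------------------------------------------------

def write_gp(gp: GaussianProcess, path, seed=None) -> None:
    np.savez(path,
             meta=json.dumps({"schema_version": SCHEMA_VERSION, "seed": seed}),
             X=gp.X, y=gp.y, lengthscales=gp.hyper.lengthscales,
             nugget=np.array(gp.hyper.nugget),
             beta_hat=gp.beta_hat, sigma2_hat=np.array(gp.sigma2_hat))


def read_gp(path) -> GaussianProcess:
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["schema_version"] != SCHEMA_VERSION:
                raise ArtifactError(f"{path}: schema version {meta['schema_version']}")
            hyper = GPHyperparams(z["lengthscales"], float(z["nugget"]))
            return GaussianProcess(z["X"], z["y"], hyper=hyper)
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as err:
        raise ArtifactError(f"{path}: unreadable GP model: {err}") from err


def write_rce(rce: RCE, directory, seed=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_basis(rce.basis, directory / "basis.npz")
    for c, gp in enumerate(rce.gps):
        write_gp(gp, directory / f"gp_{c}.npz", seed=seed)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "label": rce.label,
        "s1_context": rce.s1_context,
        "n_components": rce.n_components,
        "box": rce.box.tolist(),
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_rce(directory) -> RCE:
    directory = Path(directory)
    try:
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as err:
        raise ArtifactError(f"{directory}: unreadable RCE metadata: {err}") from err
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ArtifactError(f"{directory}: schema version {meta.get('schema_version')}")
    basis = read_basis(directory / "basis.npz")
    gps = [read_gp(directory / f"gp_{c}.npz") for c in range(meta["n_components"])]
    return RCE(basis=basis, gps=gps, box=np.array(meta["box"], dtype=float),
               label=meta.get("label", ""), s1_context=meta.get("s1_context"))


# -- observations ----------------------------------------------------------

def write_observations(obs_list, path, seed=None) -> None:
    frames = []
    for obs in obs_list:
        frames.append(pd.DataFrame({
            "channel": obs.channel,
            "s2_ms": obs.s2,
            "value": obs.values,
        }))
    _write_csv(pd.concat(frames, ignore_index=True), Path(path), "observations", seed)


def read_observations(path):
    df = _read_csv(Path(path), "observations", expected_cols=("channel", "s2_ms", "value"))
    out = []
    for channel, grp in df.groupby("channel", sort=True):
        out.append(CurveObservations(s2=grp["s2_ms"].to_numpy(float),
                                     values=grp["value"].to_numpy(float),
                                     channel=str(channel)))
    return out


def write_erp_brackets(brackets, path, seed=None) -> None:
    df = pd.DataFrame({
        "s1_ms": [b.s1 for b in brackets],
        "bracket_lower_ms": [b.lower for b in brackets],
        "bracket_width_ms": [b.width for b in brackets],
    })
    _write_csv(df, Path(path), "erp-brackets", seed)


def read_erp_brackets(path):
    df = _read_csv(Path(path), "erp-brackets",
                   expected_cols=("s1_ms", "bracket_lower_ms", "bracket_width_ms"))
    return [ERPBracket(s1=r.s1_ms, lower=r.bracket_lower_ms, width=r.bracket_width_ms)
            for r in df.itertuples()]


# -- posterior chains ------------------------------------------------------

def write_chain(result: MCMCResult, directory, map_result=None, seed=None,
                colnames=PARAM_NAMES) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(result.samples, columns=list(colnames)[:result.samples.shape[1]])
    df["log_posterior"] = result.log_prob
    _write_csv(df, directory / "samples.csv", "posterior", seed)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "acceptance_fraction": result.acceptance_fraction,
        "n_walkers": result.n_walkers,
        "n_steps": result.n_steps,
        "burn": result.burn,
        "thin": result.thin,
        "warnings": result.warnings,
    }
    if map_result is not None:
        summary["map"] = {"x": map_result.x.tolist(), "sigmas": map_result.sigmas,
                          "log_posterior": map_result.log_posterior}
    with open(directory / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
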