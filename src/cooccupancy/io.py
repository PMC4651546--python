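"""Readers, writers and posterior summary tables.

File conventions: detection histories travel as long-format CSV with
columns ``cell_id, week, Y_bobcat, Y_hare, K`` (weeks 1-based in files,
0-based internally); covariates as wide CSV keyed by ``cell_id``.  Every
CSV written here starts with a ``#`` comment line carrying the master seed
and a configuration hash, so outputs are traceable to the run that made
them; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import CovariateTable, LANDCOVER_CLASSES, PREDATOR_COVARIATES
from .mcmc import MCMCConfig, PosteriorSamples, rhat_table
from .model import DetectionHistory, INDICATOR_NAMES


def config_hash(config) -> str:
    """Short stable hash of a configuration dataclass (for output provenance)."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, seed=None, config=None, index=True) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    meta = []
    if seed is not None:
        meta.append(f"seed={seed}")
    if config is not None:
        meta.append(f"config_hash={config_hash(config)}")
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(meta) + "\n")
        df.to_csv(fh, index=index)


# ---------------------------------------------------------------------------
# detection histories


def write_detection_history(history: DetectionHistory, path, seed=None, config=None) -> None:
    n, T = history.k.shape
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(history.cell_ids, T),
            "week": np.tile(np.arange(1, T + 1), n),
            "Y_bobcat": history.y_bobcat.ravel(),
            "Y_hare": history.y_hare.ravel(),
            "K": history.k.ravel(),
        }
    )
    write_csv(df, path, seed=seed, config=config, index=False)


def read_detection_history(path) -> DetectionHistory:
    """Read and validate a long-format detection-history CSV.

    Raises ``ValueError`` naming the offence for duplicate (cell, week)
    rows, non-contiguous weeks, negative counts, or Y > K.
    """
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "week", "Y_bobcat", "Y_hare", "K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection history missing columns: {sorted(missing)}")
    if df.duplicated(["cell_id", "week"]).any():
        raise ValueError("duplicate (cell_id, week) rows in detection history")
    weeks = np.sort(df["week"].unique())
    if not np.array_equal(weeks, np.arange(1, len(weeks) + 1)):
        raise ValueError("weeks must be contiguous starting at 1")
    counts = df.groupby("cell_id")["week"].count()
    if counts.nunique() != 1:
        raise ValueError("every cell needs a row for every week")
    if (df[["Y_bobcat", "Y_hare", "K"]] < 0).any().any():
        raise ValueError("negative counts in detection history")
    if (df["Y_bobcat"] > df["K"]).any() or (df["Y_hare"] > df["K"]).any():
        raise ValueError("detection days Y exceed operating days K")
    wide = df.pivot(index="cell_id", columns="week")
    return DetectionHistory(
        y_bobcat=wide["Y_bobcat"].to_numpy(dtype=np.int64),
        y_hare=wide["Y_hare"].to_numpy(dtype=np.int64),
        k=wide["K"].to_numpy(dtype=np.int64),
        cell_ids=wide.index.to_numpy(),
    )


# ---------------------------------------------------------------------------
# covariates


def write_covariates(cov: CovariateTable, path, seed=None, config=None) -> None:
    write_csv(cov.data, path, seed=seed, config=config)


def read_covariates(path) -> CovariateTable:
    """Read an already-scaled wide covariate CSV (no grid geometry attached)."""
    df = pd.read_csv(path, comment="#", index_col="cell_id")
    expected = list(PREDATOR_COVARIATES) + list(LANDCOVER_CLASSES)
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    df = df.loc[:, expected]
    ident = pd.Series(0.0, index=df.columns)
    return CovariateTable(
        data=df, center=ident, scale=ident + 1.0, grid=None  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# posterior persistence and summaries

_TIDY_LIMIT = 2_000_000  # rows; guards against accidentally huge tidy exports


def write_posterior_draws(samples: PosteriorSamples, path, seed=None) -> None:
    """Tidy CSV of all scalar parameter draws: chain, iteration, parameter, value."""
    frames = []
    C, D = samples.n_chains, samples.n_draws
    chain = np.repeat(np.arange(C), D)
    iteration = np.tile(np.arange(D), C)
    for name, v in samples.params.items():
        if v.ndim == 2:
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "iteration": iteration, "parameter": name, "value": v.ravel()}
                )
            )
        else:
            for j in range(v.shape[2]):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": chain,
                            "iteration": iteration,
                            "parameter": f"{name}[{j}]",
                            "value": v[:, :, j].ravel(),
                        }
                    )
                )
    tidy = pd.concat(frames, ignore_index=True)
    if len(tidy) > _TIDY_LIMIT:
        raise ValueError("tidy export too large; use save_samples instead")
    write_csv(tidy, path, seed=seed, config=samples.config, index=False)


def save_samples(samples: PosteriorSamples, path) -> None:
    """Compact columnar archive of a posterior (numpy .npz)."""
    arrays = {f"param_{k}": v for k, v in samples.params.items()}
    arrays.update(
        p_hare=samples.p_hare,
        p_bobcat=samples.p_bobcat,
        group_hare=samples.group_hare,
        group_bobcat=samples.group_bobcat,
        cell_ids=samples.cell_ids,
        config_json=np.array(json.dumps(asdict(samples.config))),
    )
    if samples.z_hare is not None:
        arrays.update(z_hare=samples.z_hare, z_bobcat=samples.z_bobcat)
    np.savez_compressed(path, **arrays)


def load_samples(path) -> PosteriorSamples:
    with np.load(path, allow_pickle=False) as z:
        params = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        cfg = MCMCConfig(**json.loads(str(z["config_json"])))
        return PosteriorSamples(
            params=params,
            z_hare=z["z_hare"] if "z_hare" in z.files else None,
            z_bobcat=z["z_bobcat"] if "z_bobcat" in z.files else None,
            p_hare=z["p_hare"],
            p_bobcat=z["p_bobcat"],
            group_hare=z["group_hare"],
            group_bobcat=z["group_bobcat"],
            cell_ids=z["cell_ids"],
            config=cfg,
        )


_SLOPE_INDICATORS = {
    **{f"slopes_present[{j}]": j for j in range(5)},
    **{f"slopes_absent[{j}]": j + 5 for j in range(5)},
    **{f"beta_hare[{j}]": j + 10 for j in range(9)},
}

_PARAM_LABELS = {
    "b_hare": "hare intercept",
    "b_bobcat_present": "bobcat intercept (hare present)",
    "b_bobcat_absent": "bobcat intercept (hare absent)",
    "sigma2_hare": "hare RE variance",
    "sigma2_bobcat": "bobcat RE variance",
    **{f"slopes_present[{j}]": f"present_{c}" for j, c in enumerate(PREDATOR_COVARIATES)},
    **{f"slopes_absent[{j}]": f"absent_{c}" for j, c in enumerate(PREDATOR_COVARIATES)},
    **{f"beta_hare[{j}]": f"hare_{c}" for j, c in enumerate(LANDCOVER_CLASSES)},
}


def parameter_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary per parameter, mirroring a model-selection table.

    For slopes under indicator selection the mean/CI columns summarize the
    draws in which the term was included (``mean_included`` etc.); the
    unconditional model-averaged mean is also reported.  ``inclusion_prob``
    is the posterior mean of the slope's indicator.
    """
    w_flat = samples.flat("w")
    rows = []
    for name, label in _PARAM_LABELS.items():
        base, _, idx = name.partition("[")
        if idx:
            draws = samples.flat(base)[:, int(idx.rstrip("]"))]
        else:
            draws = samples.flat(base)
        k = _SLOPE_INDICATORS.get(name)
        if k is None:
            cond = draws
            incl = np.nan
        else:
            sel = w_flat[:, k] == 1
            incl = float(sel.mean())
            cond = draws[sel] if sel.any() else np.array([np.nan])
        rows.append(
            {
                "parameter": label,
                "mean_included": float(np.mean(cond)),
                "sd_included": float(np.std(cond, ddof=1)) if cond.size > 1 else np.nan,
                "lo95": float(np.quantile(cond, 0.025)) if np.isfinite(cond).all() else np.nan,
                "median": float(np.quantile(cond, 0.5)) if np.isfinite(cond).all() else np.nan,
                "hi95": float(np.quantile(cond, 0.975)) if np.isfinite(cond).all() else np.nan,
                "mean_model_averaged": float(np.mean(draws)),
                "inclusion_prob": incl,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    rhats = rhat_table(samples)
    table["rhat"] = [rhats.get(k, np.nan) for k in _PARAM_LABELS]
    return table


def inclusion_probabilities(samples: PosteriorSamples) -> pd.Series:
    """Posterior inclusion probability of each candidate slope."""
    return pd.Series(samples.flat("w").mean(axis=0), index=list(INDICATOR_NAMES))


def occupancy_maps(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-cell week-averaged posterior occupancy and detection summaries.

    Also reports the predator's conditional occupancy frequency among
    prey-present and prey-absent draw-weeks of each cell (the numeric
    content of conditional-occupancy maps).
    """
    zh = samples.z_hare_flat().astype(float)
    zb = samples.z_bobcat_flat().astype(float)
    ph = samples.p_hare_full()
    pb = samples.p_bobcat_full()
    hare_present = zh == 1
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        # cells never seen in one prey state yield all-NaN slices by design
        warnings.simplefilter("ignore", RuntimeWarning)
        cond1 = np.where(hare_present, zb, np.nan)
        cond0 = np.where(~hare_present, zb, np.nan)
        df = pd.DataFrame(
            {
                "psi_hare": zh.mean(axis=(0, 2)),
                "psi_hare_sd": zh.mean(axis=2).std(axis=0, ddof=1),
                "psi_bobcat": zb.mean(axis=(0, 2)),
                "psi_bobcat_sd": zb.mean(axis=2).std(axis=0, ddof=1),
                "p_hare": ph.mean(axis=(0, 2)),
                "p_bobcat": pb.mean(axis=(0, 2)),
                "psi_bobcat_hare_present": np.nanmean(cond1, axis=(0, 2)),
                "psi_bobcat_hare_absent": np.nanmean(cond0, axis=(0, 2)),
            },
            index=pd.Index(samples.cell_ids, name="cell_id"),
        )
    return df


def summarize_posterior(samples: PosteriorSamples) -> dict[str, pd.DataFrame]:
    """All standard posterior summaries keyed by table name."""
    return {
        "parameters": parameter_table(samples),
        "inclusion": inclusion_probabilities(samples).to_frame("inclusion_prob"),
        "occupancy_maps": occupancy_maps(samples),
    }
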