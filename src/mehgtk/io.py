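"""File round-tripping, configuration and run manifests.

All tabular files are comma-separated UTF-8 text with a mandatory header
row and '.' decimals.  Writes are atomic (write to a temporary file in
the destination directory, then rename), so interrupted runs never leave
partial files at final paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .inference import MCMCConfig, Priors
from .synthetic_data import GeneratorConfig, stratum_defaults
from .tk_model import TKParams

__all__ = [
    "COHORT_COLUMNS",
    "atomic_write_text",
    "write_table",
    "read_cohort",
    "write_cohort",
    "write_chains",
    "read_chains",
    "write_summary",
    "load_config",
    "RunManifest",
    "write_manifest",
]

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "weight_kg",
    "blood_mehg_ug_per_L",
    "intake_ug_per_kg_day",
]


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a same-directory temp file and rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    write_table(df[COHORT_COLUMNS], path)


def write_chains(chainset, path) -> None:
    """Long-format scalar-parameter draws: ``chain,iteration,parameter,value``."""
    write_table(chainset.to_frame(), path)


def read_chains(path) -> dict:
    """Read a long-format chain file back into parameter -> (chains, draws) arrays."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for name, g in df.groupby("parameter", sort=False):
        wide = g.pivot(index="chain", columns="iteration", values="value")
        out[str(name)] = wide.to_numpy()
    return out


def write_summary(summaries: dict[str, pd.DataFrame], path) -> None:
    """Summary blocks (one per stratum) as a single delimited table."""
    blocks = []
    for stratum, df in summaries.items():
        block = df.reset_index()
        block.insert(0, "stratum", stratum)
        blocks.append(block)
    write_table(pd.concat(blocks, ignore_index=True), path)


# ---------------------------------------------------------------------------
# configuration

def _build_dataclass(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise KeyError(f"invalid value in [{section}]: {exc}") from exc


def load_config(path=None):
    """Load a YAML run configuration.

    Recognized sections: ``mcmc`` (MCMCConfig fields), ``priors`` (Priors
    fields, pairs given as 2-lists) and ``generator`` (GeneratorConfig
    fields plus optional ``stratum`` preset and ``tk_true`` as a 3-list
    [Abs, frac_b, V_b]).  Missing sections get defaults; unknown keys are
    an error naming the key.
    """
    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise KeyError("config root must be a mapping")
    unknown = set(raw) - {"mcmc", "priors", "generator"}
    if unknown:
        raise KeyError(f"unknown config section(s): {sorted(unknown)}")

    mcmc = _build_dataclass(MCMCConfig, dict(raw.get("mcmc") or {}), "mcmc")

    pdata = dict(raw.get("priors") or {})
    for key in list(pdata):
        if key.endswith("_bounds"):
            pdata[key] = tuple(pdata[key])
    priors = _build_dataclass(Priors, pdata, "priors")

    gdata = dict(raw.get("generator") or {})
    stratum = gdata.pop("stratum", "total")
    if "tk_true" in gdata:
        a, fb, vb = gdata["tk_true"]
        gdata["tk_true"] = TKParams(abs_fraction=a, frac_blood=fb, blood_volume=vb)
    base = stratum_defaults(stratum)
    names = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(gdata) - names
    if unknown:
        raise KeyError(f"unknown key(s) in [generator]: {sorted(unknown)}")
    try:
        generator = dataclasses.replace(base, **gdata)
    except ValueError as exc:
        raise KeyError(f"invalid value in [generator]: {exc}") from exc
    return mcmc, priors, generator


# ---------------------------------------------------------------------------
# run manifests

@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config: dict
    seed: int
    inputs: dict[str, str]
    outputs: list[str]
    timestamp: str = ""

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = datetime.now(timezone.utc).isoformat()
        return json.dumps(d, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int, inputs, outputs) -> Path:
    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        inputs={str(p): _sha256(p) for p in inputs},
        outputs=[str(p) for p in outputs],
    )
    path = Path(out_dir) / "manifest.json"
    atomic_write_text(path, manifest.to_json() + "\n")
    return path
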