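"""One-command orchestration: edit -> classes -> model -> chain -> summaries.

A :class:`RunConfig` (plain YAML) names the input record and pedigree files
and the output directory; :func:`run_all` runs every stage, writes each
artifact as delimited text or JSON, and finishes with a manifest of content
hashes.  All randomness flows from the single configured seed, so the same
config reproduces the same manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .pedigree import read_pedigree, a_inverse
from .phenotypes import EditConfig, apply_edits, assign_classes, describe_structure
from .model import build_model_frame
from .gibbs import GibbsConfig, run_chain
from .posterior import summarize_store, export_traces
from .daily_corr import precorrect, daily_correlations, average_daily_correlation, correlation_table

log = logging.getLogger("tdgibbs.pipeline")


@dataclass
class RunConfig:
    """Everything one analysis run needs, as plain data."""

    records: str
    pedigree: str
    outdir: str
    edits: EditConfig = field(default_factory=EditConfig)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    as_order: int = 6
    hy_order: int = 5
    account_inbreeding: bool = True
    env_mode: str = "pooled"
    corr_window_days: int = 15
    corr_min_n: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "edits" in raw:
            raw["edits"] = EditConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw["edits"].items()
                }
            )
        if "gibbs" in raw:
            raw["gibbs"] = GibbsConfig(**raw["gibbs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Artifacts: ``edit_report.json``, class maps, the id-recode map, the
    covariance sample store, the posterior summary table, trace/density
    exports, the daily-correlation table, and ``manifest.json``.  A stage
    failure aborts with the stage name; artifacts of earlier stages are
    left in place.
    """
    for p in (config.records, config.pedigree):
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config: %s", json.dumps(config.to_dict()))

    stage = "prep"
    try:
        records = pd.read_csv(config.records)
        edited, report = apply_edits(records, config.edits)
        with open(out / "edit_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        classes = assign_classes(edited)
        classes.write_maps(str(out) + "/")

        stage = "pedigree"
        ped = read_pedigree(config.pedigree)
        rel = a_inverse(ped, account_inbreeding=config.account_inbreeding)
        rel.write_id_map(out / "id_map.tsv")
        with open(out / "structure.json", "w") as fh:
            json.dump(describe_structure(edited, ped), fh, indent=1)

        stage = "fit"
        frame = build_model_frame(
            edited, classes, rel, as_order=config.as_order, hy_order=config.hy_order
        )
        store = run_chain(
            frame, config.gibbs, checkpoint_dir=out / "checkpoints", log=log.info
        )
        store.save(out / "samples.csv")

        stage = "summarize"
        summarize_store(store, env_mode=config.env_mode).to_csv(
            out / "summary.csv", index=False
        )
        traces, density = export_traces(store, env_mode=config.env_mode)
        traces.to_csv(out / "traces.csv", index=False)
        density.to_csv(out / "density.csv", index=False)

        stage = "corr"
        adjusted = precorrect(edited, classes)
        corrs = daily_correlations(
            adjusted, window_days=config.corr_window_days, min_n=config.corr_min_n
        )
        correlation_table(corrs).to_csv(out / "daily_correlations.csv", index=False)
        with open(out / "average_correlations.json", "w") as fh:
            json.dump(
                {"-".join(k): v for k, v in average_daily_correlation(corrs).items()},
                fh,
                indent=1,
            )
    except Exception as err:
        log.error("stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    artifacts = sorted(
        p for p in out.iterdir() if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "config": config.to_dict(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
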