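"""File formats and the end-to-end pipeline.

Range data use the Lagrange/PHYLIP-style dialect: a header line
``ntaxa nareas`` followed by one ``label<whitespace>binary-string`` line
per taxon. Characters are '1' (presence), '0' (absence) or '?'
(unknown); any '?' marks the whole observation as ambiguous, with
presences taken from the '1' positions — the coding used for fossils,
whose absences are unknowable. Latitude tables are TSV with columns
``label``, ``latitude_degrees``, ``age_Ma``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .dec import DECModel, TipRangeObservation
from .events import events_from_ancestral_table, events_to_frame, summarize_events
from .geography import GeoModel
from .latitude import LatitudeTrendModel
from .trees import read_tree

__all__ = [
    "read_ranges",
    "write_ranges",
    "read_latitude_table",
    "write_latitude_table",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_ranges(path, geo: GeoModel) -> dict[str, TipRangeObservation]:
    """Parse a Lagrange-style range file into tip observations."""
    obs: dict[str, TipRangeObservation] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ValueError(f"{path}: malformed header (need 'ntaxa nareas')")
        ntaxa, nareas = int(header[0]), int(header[1])
        if nareas != geo.n_areas:
            raise ValueError(
                f"{path}: file has {nareas} areas, geographic model has {geo.n_areas}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'label pattern'")
            label, pattern = parts
            if len(pattern) != nareas:
                raise ValueError(
                    f"{path}:{lineno}: pattern width {len(pattern)} != {nareas}"
                )
            mask = 0
            ambiguous = False
            for i, ch in enumerate(pattern):
                if ch == "1":
                    mask |= 1 << i
                elif ch == "?":
                    ambiguous = True
                elif ch != "0":
                    raise ValueError(f"{path}:{lineno}: bad character {ch!r}")
            if mask == 0:
                raise ValueError(f"{path}:{lineno}: all-absent range for {label!r}")
            obs[label] = TipRangeObservation(label, mask, ambiguous)
    if len(obs) != ntaxa:
        raise ValueError(
            f"{path}: header says {ntaxa} taxa, found {len(obs)}"
        )
    return obs


def write_ranges(path, ranges: Mapping[str, tuple[int, bool]], geo: GeoModel
                 ) -> None:
    """Write ranges; ambiguous taxa get '?' in every non-presence position."""
    with open(path, "w") as fh:
        fh.write(f"{len(ranges)} {geo.n_areas}\n")
        for label in ranges:
            mask, ambiguous = ranges[label]
            chars = []
            for a in range(geo.n_areas):
                if mask >> a & 1:
                    chars.append("1")
                else:
                    chars.append("?" if ambiguous else "0")
            fh.write(f"{label}\t{''.join(chars)}\n")


def read_latitude_table(path) -> dict[str, float]:
    """label -> latitude (degrees); the age column is informational."""
    data: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            li = header.index("label")
            vi = header.index("latitude_degrees")
        except ValueError as exc:
            raise ValueError(f"{path}: missing required columns") from exc
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            data[parts[li]] = float(parts[vi])
    return data


def write_latitude_table(path, rows: Iterable[tuple[str, float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("label\tlatitude_degrees\tage_Ma\n")
        for label, lat, age in rows:
            fh.write(f"{label}\t{lat:.6f}\t{age:.6f}\n")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    tree: str
    ranges: str
    geo: str
    out: str
    latitudes: str | None = None
    ambiguous_fossils: bool = True
    include_fossils: bool = True
    run_latitude: bool = False
    mcmc_generations: int = 100_000
    seed: int = 0
    top_k: int = 3
    fit_starts: int = 3
    fit_maxiter: int = 200

    def validate(self) -> None:
        for name in ("tree", "ranges", "geo"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.run_latitude:
            if self.latitudes is None or not Path(self.latitudes).exists():
                raise FileNotFoundError("latitude table required for the latitude stage")


def run_pipeline(config: RunConfig) -> dict:
    """fit -> ancestral ranges -> events -> summaries (-> latitude MCMC).

    Writes TSV tables, a JSON fit report, and a JSON manifest to
    ``config.out``; returns the manifest. Any stage failure aborts with
    the stage name recorded in a partial manifest.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "versions": _versions(),
        "stages": {},
    }
    stage = "setup"
    try:
        geo = GeoModel.load(config.geo)
        tree = read_tree(config.tree)
        observations = read_ranges(config.ranges, geo)
        if not config.include_fossils:
            fossil_labels = {t.label for t in tree.fossil_tips()}
            tree = tree.prune_tips(fossil_labels)
            observations = {k: v for k, v in observations.items()
                            if k not in fossil_labels}
            logger.info("pruned %d fossil tips", len(fossil_labels))
        if not config.ambiguous_fossils:
            observations = {
                k: TipRangeObservation(v.label, v.observed_areas, False)
                for k, v in observations.items()
            }

        stage = "fit"
        t0 = time.perf_counter()
        model = DECModel(tree, observations, geo)
        default_starts = [(0.01, 0.01), (0.1, 0.02), (0.001, 0.005)]
        results = model.fit(starts=default_starts[:max(1, config.fit_starts)],
                            maxiter=config.fit_maxiter)
        manifest["stages"]["fit"] = {
            "seconds": round(time.perf_counter() - t0, 2),
            **results.to_json_dict(),
        }
        with open(outdir / "dec_fit.json", "w") as fh:
            json.dump(results.to_json_dict(), fh, indent=2)
        logger.info("DEC fit: d=%.5f e=%.5f lnL=%.3f",
                    results.params.d, results.params.e, results.llf)

        stage = "ancestral"
        t0 = time.perf_counter()
        table = results.ancestral_ranges()
        frame = table.to_frame(top_k=config.top_k)
        frame.to_csv(outdir / "ancestral_ranges.tsv", sep="\t", index=False,
                     float_format="%.6f")
        manifest["stages"]["ancestral"] = {
            "seconds": round(time.perf_counter() - t0, 2),
            "n_nodes": len(frame),
        }

        stage = "events"
        events = events_from_ancestral_table(tree, table, geo)
        events_to_frame(events, geo).to_csv(
            outdir / "events.tsv", sep="\t", index=False, float_format="%.4f")
        summary = summarize_events(events, geo)
        summary.to_frame().to_csv(
            outdir / "event_summary.tsv", sep="\t", index=False)
        manifest["stages"]["events"] = {
            "n_events": len(events),
            "n_vicariance": summary.n_vicariance,
            "n_dispersal": summary.n_dispersal,
            "n_extirpation": summary.n_extirpation,
            "by_class": summary.by_class,
            "extirpations_per_bin": summary.extirpations_per_bin,
        }

        if config.run_latitude:
            stage = "latitude"
            t0 = time.perf_counter()
            data = read_latitude_table(config.latitudes)
            lat_model = LatitudeTrendModel(tree, data)
            lat_results = lat_model.fit_mcmc(
                n_generations=config.mcmc_generations, seed=config.seed)
            span = lat_results.span_through_time()
            span.to_csv(outdir / "latitude_span.tsv", sep="\t", index=False,
                        float_format="%.4f")
            manifest["stages"]["latitude"] = {
                "seconds": round(time.perf_counter() - t0, 2),
                "n_samples": len(lat_results.samples),
                "sigma2_mean": float(lat_results.sigma2_samples.mean()),
                "mu_mean": [float(v) for v in lat_results.mu_samples.mean(axis=0)],
                "acceptance": {k: float(v) for k, v in
                               lat_results.acceptance.items()},
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _versions() -> dict:
    import scipy
    import pandas
    from . import __version__

    return {
        "paleorange": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
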