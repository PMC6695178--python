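"""End-to-end orchestration: filter -> borders -> frequencies -> summaries -> ratios.

A run is described by a single declarative config (YAML or an in-memory
:class:`RunConfig`); outputs are fixed-column TSV files plus a manifest
recording inputs, seed, per-stage record counts and a SHA-256 checksum
of every product, so that re-running an identical config reproduces
identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .amino_acids import default_scheme
from .border_uncertainty import MonteCarloTable, PerturbationConfig, monte_carlo_f
from .composition_stats import (
    FrequencyTable,
    compute_f,
    group_frequencies,
    running_average,
    sampling_uncertainty,
    sigma_f,
)
from .diversity_cost import cost_series, diversity_series, load_cost_table
from .record_store import (
    DEFAULT_CRITERIA,
    FilterCriteria,
    HelixKind,
    MPRecord,
    apply_filter,
    parse_fixture,
)
from .universal_ratios import (
    AncestralModel,
    extrapolate_composition,
    fit_all,
    fits_to_frame,
    taxon_points,
)


class PipelineConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RatioSettings:
    n_min: int = 2
    n_max: int = 7
    reference: str = "F"
    model: str = "exp"
    f_phe: Tuple[float, ...] = (-2.24, 0.0)
    k: Tuple[int, ...] = (10, 16)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    inputs: Mapping[str, Path]  # taxon name -> fixture path
    out_dir: Path
    n_max: int = 19
    criteria: FilterCriteria = DEFAULT_CRITERIA
    perturbation: Optional[PerturbationConfig] = None
    cost_table_path: Optional[Path] = None
    ratios: RatioSettings = field(default_factory=RatioSettings)
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs:
            raise PipelineConfigError("no input fixtures configured")
        for taxon, path in self.inputs.items():
            if not Path(path).exists():
                raise PipelineConfigError(f"input for {taxon!r} not found: {path}")
        if self.cost_table_path is not None and not Path(self.cost_table_path).exists():
            raise PipelineConfigError(f"cost table not found: {self.cost_table_path}")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Read a YAML run config; CLI flags may override individual values."""
    raw = yaml.safe_load(Path(path).read_text())
    crit_kwargs = {}
    fsec = raw.get("filter", {})
    if "tags" in fsec:
        crit_kwargs["allowed_location_tags"] = frozenset(fsec["tags"])
    if "existence" in fsec:
        crit_kwargs["allowed_existence_codes"] = frozenset(int(c) for c in fsec["existence"])
    if "taxon" in fsec:
        crit_kwargs["taxon"] = fsec["taxon"]
    if "helix_kinds" in fsec:
        crit_kwargs["allowed_helix_kinds"] = frozenset(HelixKind(k) for k in fsec["helix_kinds"])
    if "substring_match" in fsec:
        crit_kwargs["substring_match"] = bool(fsec["substring_match"])
    perturbation = None
    if "monte_carlo" in raw:
        mc = raw["monte_carlo"]
        perturbation = PerturbationConfig(
            sd=float(mc.get("sd", 3.8)),
            max_shrink=int(mc.get("max_shrink", 5)),
            replicates=int(mc.get("replicates", 100)),
            seed=mc.get("seed", raw.get("seed", 0)),
        )
    rsec = raw.get("ratios", {})
    ratios = RatioSettings(
        n_min=int(rsec.get("n_min", 2)),
        n_max=int(rsec.get("n_max", 7)),
        reference=str(rsec.get("reference", "F")),
        model=str(rsec.get("model", "exp")),
        f_phe=tuple(float(v) for v in rsec.get("f_phe", (-2.24, 0.0))),
        k=tuple(int(v) for v in rsec.get("k", (10, 16))),
    )
    return RunConfig(
        inputs={t: Path(p) for t, p in raw["inputs"].items()},
        out_dir=Path(raw.get("out_dir", "tmscape_out")),
        n_max=int(raw.get("n_max", 19)),
        criteria=FilterCriteria(**crit_kwargs) if crit_kwargs else DEFAULT_CRITERIA,
        perturbation=perturbation,
        cost_table_path=Path(raw["cost_table"]) if raw.get("cost_table") else None,
        ratios=ratios,
        seed=int(raw.get("seed", 0)),
    )


def size_distribution(records: Sequence[MPRecord]) -> pd.DataFrame:
    """Protein and total-helix counts per n (empty frame for no input)."""
    counts: Dict[int, int] = {}
    for rec in records:
        counts[rec.n] = counts.get(rec.n, 0) + 1
    rows = [(n, c, n * c) for n, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["n", "proteins", "helices"])


def size_fraction(
    records: Sequence[MPRecord], lo: int, hi: int, base_min: int = 2
) -> float:
    """Share of proteins with lo <= n <= hi among those with n >= base_min."""
    base = [r for r in records if r.n >= base_min]
    if not base:
        return float("nan")
    hit = [r for r in base if lo <= r.n <= hi]
    return len(hit) / len(base)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and return the output manifest.

    Products (per run, in ``out_dir``): frequency.tsv (long-format f with
    the sampling-uncertainty column), mc_frequency.tsv (if Monte-Carlo is
    configured, with the replicate-SD column), summary.tsv (sigma_f,
    E_H, cost and their running averages per taxon and n), groups.tsv,
    size_distribution.tsv, fits.tsv and ancestral.tsv (with >= 3 taxa),
    and manifest.json.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    costs = load_cost_table(config.cost_table_path)

    stage_counts: Dict[str, dict] = {}
    tables: Dict[str, FrequencyTable] = {}
    freq_frames: List[pd.DataFrame] = []
    mc_frames: List[pd.DataFrame] = []
    group_frames: List[pd.DataFrame] = []
    summary_frames: List[pd.DataFrame] = []
    size_frames: List[pd.DataFrame] = []

    for taxon, path in config.inputs.items():
        with open(path) as handle:
            records = parse_fixture(handle)
        result = apply_filter(records, config.criteria)
        stage_counts[taxon] = {
            "parsed": len(records),
            "retained": len(result.records),
            "removed": dict(result.removed),
        }
        if not result.records:
            raise PipelineConfigError(f"stage filter[{taxon}]: no records retained")
        table = compute_f(result.records, n_max=config.n_max)
        stage_counts[taxon]["skipped_ambiguous"] = table.skipped_ambiguous

        if config.perturbation is not None:
            mc = monte_carlo_f(result.records, config.perturbation, n_max=config.n_max)
            mc_frame = mc.table.to_frame(taxon)
            sd_long = mc.f_sd.stack().rename("replicate_sd").reset_index()
            sd_long.columns = ["n", "AA", "replicate_sd"]
            mc_frame = mc_frame.merge(sd_long, on=["n", "AA"])
            mc_frames.append(mc_frame)
            analysis_table = mc.table  # headgroup-inclusive dataset for summaries
        else:
            analysis_table = table
        tables[taxon] = analysis_table

        frame = table.to_frame(taxon)
        unc = sampling_uncertainty(table).stack().rename("uncertainty").reset_index()
        unc.columns = ["n", "AA", "uncertainty"]
        freq_frames.append(frame.merge(unc, on=["n", "AA"]))

        groups = group_frequencies(analysis_table, scheme)
        groups.insert(0, "taxon", taxon)
        group_frames.append(groups.reset_index(names="n"))

        sf = sigma_f(analysis_table)
        eh = diversity_series(analysis_table)
        cost = cost_series(analysis_table, costs)
        summary = pd.DataFrame(
            {
                "taxon": taxon,
                "n": sf.index,
                "sigma_f": sf.values,
                "E_H": eh.values,
                "cost": cost.values,
                "sigma_f_runavg": running_average(sf).values,
                "E_H_runavg": running_average(eh).values,
                "cost_runavg": running_average(cost).values,
            }
        )
        summary_frames.append(summary)

        sizes = size_distribution(result.records)
        sizes.insert(0, "taxon", taxon)
        size_frames.append(sizes)

    products: Dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        _write_tsv(frame, path)
        products[name] = path

    emit("frequency.tsv", pd.concat(freq_frames, ignore_index=True))
    if mc_frames:
        emit("mc_frequency.tsv", pd.concat(mc_frames, ignore_index=True))
    emit("groups.tsv", pd.concat(group_frames, ignore_index=True))
    emit("summary.tsv", pd.concat(summary_frames, ignore_index=True))
    emit("size_distribution.tsv", pd.concat(size_frames, ignore_index=True))

    if len(tables) >= 3:
        points = taxon_points(tables, n_range=(config.ratios.n_min, config.ratios.n_max))
        fits = fit_all(points, reference=config.ratios.reference, model=config.ratios.model)
        emit("fits.tsv", fits_to_frame(fits))
        rows = []
        for f_phe, k in zip(config.ratios.f_phe, config.ratios.k):
            model = AncestralModel(
                fits=fits, k=k, f_phe=f_phe, reference=config.ratios.reference
            )
            comp, total = extrapolate_composition(model)
            for aa, value in comp.items():
                rows.append((aa, f_phe, k, value))
            rows.append(("SUM", f_phe, k, total))
        emit("ancestral.tsv", pd.DataFrame(rows, columns=["AA", "f_phe", "k", "f"]))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {t: str(p) for t, p in config.inputs.items()},
        "stages": stage_counts,
        "products": {name: _sha256(path) for name, path in products.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
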