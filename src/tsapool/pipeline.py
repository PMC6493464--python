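"""End-to-end orchestration: normalize -> summarize -> identify -> prioritize
-> coverage, with a manifest recording inputs, configuration and timings so a
run can be reproduced exactly."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import coverage as cov
from . import io as tio
from .identification import AntigenProfile, build_profiles, filter_targets
from .io import (
    CohortMetadata,
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
    TissueWeightTable,
)
from .normalization import compute_size_factors, normalize
from .prioritization import PrioritizedTarget, prioritize

__all__ = ["RunManifest", "PipelineResult", "run_all"]


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    output_paths: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    normalized: CountMatrix
    profiles: list[AntigenProfile]
    pool: list[AntigenProfile]
    ranked: list[PrioritizedTarget]
    cocktail: cov.CocktailReport | None
    manifest: RunManifest


def _digest_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    raw: CountMatrix,
    meta: CohortMetadata,
    annot: GeneAnnotation,
    weights: TissueWeightTable | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    top: int = 5,
    greedy: bool = False,
    pseudocount: float = 0.0,
    ippae_denominator: float | None = None,
    allow_unweighted: bool = False,
    input_paths: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write all artifacts.

    ``ippae_denominator`` pins the adverse-event index normalization to an
    external reference pool instead of this run's pool maximum.  ``top``
    selects the cocktail size (0 disables coverage analysis).
    """
    cfg = cfg or PipelineConfig()
    weights = weights or tio.default_weights()
    weights = weights.validate_against(meta.tissues, allow_unweighted=allow_unweighted)
    manifest = RunManifest(
        config={f.name: getattr(cfg, f.name) for f in fields(cfg)},
        input_digests={k: _digest_file(v) for k, v in (input_paths or {}).items()},
        seed=cfg.rng_seed,
    )

    def timed(stage):
        t0 = time.perf_counter()

        def done():
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 4)

        return done

    done = timed("normalize")
    sf = compute_size_factors(raw, pseudocount=pseudocount)
    norm = normalize(raw, sf)
    done()

    done = timed("identify")
    profiles = build_profiles(norm, meta, annot, weights, cfg)
    pool = filter_targets(profiles, cfg)
    done()

    done = timed("prioritize")
    ranked = prioritize(
        pool, weights, meta.n_tumor, cfg, denominator=ippae_denominator
    )
    done()

    cocktail = None
    if top and ranked:
        done = timed("coverage")
        k = min(top, len(ranked))
        sets = cov.coverage_sets(ranked)
        cocktail = cov.greedy_cocktail(
            sets,
            meta.n_tumor,
            k,
            mode="greedy" if greedy else "rank",
            dtpf={t.gene_id: t.dtpf for t in ranked},
            cohort=frozenset(meta.tumor_samples),
        )
        done()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "normalized": outdir / "normalized.tsv",
            "ranked": outdir / "ranked.tsv",
            "manifest": outdir / "manifest.json",
        }
        tio.write_count_matrix(norm, paths["normalized"])
        tio.write_target_report(ranked, paths["ranked"])
        if cocktail is not None:
            paths["cocktail"] = outdir / "cocktail.tsv"
            _write_cocktail(cocktail, paths["cocktail"])
        manifest.output_paths = {k: str(v) for k, v in paths.items()}
        manifest.write(paths["manifest"])

    return PipelineResult(
        normalized=norm,
        profiles=profiles,
        pool=pool,
        ranked=ranked,
        cocktail=cocktail,
        manifest=manifest,
    )


def _write_cocktail(report: cov.CocktailReport, path: Path) -> None:
    lines = ["metric\tvalue"]
    lines.append(f"mode\t{report.mode}")
    lines.append("genes\t" + ",".join(report.genes))
    lines.append(
        "cumulative_coverage_pct\t"
        + ",".join(f"{100 * f:.1f}" for f in report.cumulative_fractions)
    )
    for k in sorted(report.multiplicity):
        lines.append(f"covered_by_exactly_{k}\t{report.multiplicity[k]}")
    lines.append(f"total_coverage_pct\t{100 * report.total_coverage:.1f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
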