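"""Evaluation orchestration and table serialisation.

``run_evaluation`` wires the whole pipeline: load ontology and annotations,
restrict code sets to the finding subhierarchy, compare every requested coder
pairwise and against the reference, micro-average the coders, and (when
ratings are supplied) tabulate the qualitative summary and the
distance-vs-rating concordance.  Tables are written both as full-precision
CSV and as a markdown report in which percentages are rounded to integers
with round-half-away-from-zero, so rendered reports are bit-stable across
platforms.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, annotations as ann
from .agreement import AgreementTable
from .ontology import OntologyGraph, load_edge_list, load_rf2_relationships

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> float:
    """Round halves away from zero (platform-stable display rounding)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def _display(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if str(col).startswith("pct_"):
            out[col] = out[col].map(round_half_away)
    return out


def dataframe_to_markdown(df: pd.DataFrame, title: str = "") -> str:
    """Minimal GitHub-style markdown table (no external table dependency)."""
    df = _display(df.reset_index() if df.index.name else df)
    cols = [str(c) for c in df.columns]
    lines = []
    if title:
        lines += [f"### {title}", ""]
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("| " + " | ".join("---" for _ in cols) + " |")
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append("NA" if math.isnan(v) else f"{v:g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


@dataclass
class EvaluationConfig:
    ontology: str
    annotations: str
    reference: str = "GS"
    coders: list[str] = field(default_factory=list)
    ratings: str | None = None
    blocklist: str | None = None
    finding_root: str | None = None
    direction: str = "symmetric"
    rf2: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


@dataclass
class EvaluationResult:
    """All tables produced by one evaluation run."""

    pairwise: dict[tuple[str, str], AgreementTable]
    micro: AgreementTable
    per_item: pd.DataFrame
    qualitative: pd.DataFrame | None = None
    rating_concordance: pd.DataFrame | None = None


def run_evaluation(
    config: EvaluationConfig, out_dir: str | Path | None = None
) -> EvaluationResult:
    """Run the full distance-based (and optional qualitative) evaluation."""
    loader = load_rf2_relationships if config.rf2 else load_edge_list
    graph = loader(config.ontology)
    if config.finding_root is not None:
        finding_root = config.finding_root
    else:
        roots = graph.roots
        if len(roots) != 1:
            raise ValueError(
                "finding_root must be specified for a multi-rooted ontology"
            )
        (finding_root,) = roots
    records = ann.read_annotations(config.annotations)
    if config.blocklist:
        blocked = ann.read_blocklist(config.blocklist)
        records = ann.apply_blocklist(records, blocked)
        logger.info("blocklist removed items: %d ids listed", len(blocked))
    records = ann.filter_records(records, graph, finding_root)

    coders = config.coders or sorted(
        {r.coder_id for r in records} - {config.reference}
    )
    pairwise: dict[tuple[str, str], AgreementTable] = {}
    per_item_rows = []
    # coder-vs-coder pairs, then each coder vs the reference
    pairs = list(itertools.combinations(coders, 2)) + [
        (c, config.reference) for c in coders
    ]
    for x, y in pairs:
        comparisons, excl = agreement.compare_coders(
            records, x, y, graph, direction=config.direction
        )
        pairwise[(x, y)] = agreement._tabulate(comparisons, f"{x} vs {y}", excl.excluded)
        per_item_rows.extend(
            {
                "item_id": c.item_id,
                "coder_x": c.coder_x,
                "coder_y": c.coder_y,
                "n_x": c.n_x,
                "n_y": c.n_y,
                "stratum": c.stratum,
                "distance": c.value,
                "band": c.band,
            }
            for c in comparisons
        )
    micro = agreement.micro_average(
        records, coders, config.reference, graph, direction=config.direction
    )
    per_item = pd.DataFrame(per_item_rows)

    qualitative = rating_concordance = None
    if config.ratings:
        ratings = ann.read_ratings(config.ratings)
        qualitative = agreement.qualitative_summary(ratings, coders)
        rating_concordance = agreement.distance_vs_rating(
            records, ratings, config.reference, graph, direction=config.direction
        )

    result = EvaluationResult(
        pairwise=pairwise,
        micro=micro,
        per_item=per_item,
        qualitative=qualitative,
        rating_concordance=rating_concordance,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def write_report(result: EvaluationResult, out_dir: str | Path) -> list[Path]:
    """Write every table as full-precision CSV plus one markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    md_parts = ["# Coding evaluation report", ""]
    for (x, y), table in result.pairwise.items():
        df = table.to_dataframe()
        path = out / f"table_agreement_{x}_vs_{y}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        md_parts.append(dataframe_to_markdown(df, title=f"Agreement: {table.label}"))
    micro_df = result.micro.to_dataframe()
    path = out / "table_agreement_micro.csv"
    micro_df.to_csv(path, index=False)
    written.append(path)
    md_parts.append(dataframe_to_markdown(micro_df, title=result.micro.label))
    path = out / "per_item_distances.csv"
    result.per_item.to_csv(path, index=False)
    written.append(path)
    if result.qualitative is not None:
        path = out / "table_qualitative.csv"
        result.qualitative.to_csv(path, index=False)
        written.append(path)
        md_parts.append(
            dataframe_to_markdown(result.qualitative, title="Qualitative summary")
        )
    if result.rating_concordance is not None:
        path = out / "table_rating_concordance.csv"
        result.rating_concordance.to_csv(path, index=False)
        written.append(path)
        md_parts.append(
            dataframe_to_markdown(
                result.rating_concordance, title="Distance vs rating concordance"
            )
        )
    report = out / "report.md"
    report.write_text("\n".join(md_parts), encoding="utf-8")
    written.append(report)
    return written
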