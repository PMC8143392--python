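"""Human-readable scenario reports: the AND/OR transfer summary.

Transfers present in every enumerated trophic scenario form the AND
block (obligatory exchanges); the remaining active transfers are
partitioned into OR groups of interchangeable alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .community import CommunityModel
from .symbiosis import ScenarioSet

__all__ = ["ScenarioReport", "EmptyReportError", "summarize_scenarios", "write_report"]


class EmptyReportError(ValueError):
    """Raised when asked to summarize an empty scenario set."""


@dataclass(frozen=True)
class ScenarioReport:
    essential: tuple[str, ...]  # AND block, sorted
    or_groups: tuple[tuple[str, ...], ...]  # OR blocks, members sorted
    objective_counts: tuple[int, ...]  # per scenario, by rank
    nitrogen_carriers: tuple[str, ...]  # N-carrying transfers seen active

    def to_text(self) -> str:
        lines = ["Transfer scenario summary", "========================="]
        lines.append(f"scenarios: {len(self.objective_counts)}; "
                     f"objective counts: {list(self.objective_counts)}")
        lines.append("")
        lines.append("Obligatory transfers (AND):")
        for t in self.essential:
            lines.append(f"  AND {t}")
        if not self.essential:
            lines.append("  (none)")
        lines.append("")
        lines.append("Alternative transfers (OR groups):")
        for grp in self.or_groups:
            lines.append("  (" + " OR ".join(grp) + ")")
        if not self.or_groups:
            lines.append("  (none)")
        lines.append("")
        lines.append("Nitrogen carriers: " + (", ".join(self.nitrogen_carriers) or "(none)"))
        return "\n".join(lines) + "\n"


def summarize_scenarios(
    scenario_set: ScenarioSet,
    community: CommunityModel | None = None,
    flux_threshold: float = 1e-6,
) -> ScenarioReport:
    """Build the AND/OR report from an enumerated scenario set.

    Nitrogen carriers (transfers of N-containing metabolites observed
    carrying flux) are reported when the community is supplied.
    """
    if not scenario_set.scenarios:
        raise EmptyReportError("cannot summarize an empty scenario set")
    carriers: set[str] = set()
    if community is not None:
        nitrogenous = {t.id for t in community.transfers if t.n_nitrogen > 0}
        for s in scenario_set.scenarios:
            for tid in nitrogenous:
                if s.fluxes.get(tid, 0.0) > flux_threshold:
                    carriers.add(tid)
    return ScenarioReport(
        essential=tuple(sorted(scenario_set.essential_transfers)),
        or_groups=tuple(tuple(sorted(g)) for g in scenario_set.alternate_groups),
        objective_counts=tuple(s.objective_count for s in scenario_set.scenarios),
        nitrogen_carriers=tuple(sorted(carriers)),
    )


def write_report(
    report: ScenarioReport, scenario_set: ScenarioSet, out_dir: str | Path
) -> Path:
    """Write scenario table (TSV), grouping summary (JSON) and plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "rank": s.rank,
            "objective_count": s.objective_count,
            "active_transfers": ";".join(sorted(s.active_transfers)),
        }
        for s in scenario_set.scenarios
    ]
    pd.DataFrame(rows, columns=["rank", "objective_count", "active_transfers"]).to_csv(
        out / "scenarios.tsv", sep="\t", index=False
    )
    summary = {
        "mode": scenario_set.mode,
        "complete": scenario_set.complete,
        "n_scenarios": len(scenario_set.scenarios),
        "essential": list(report.essential),
        "or_groups": [list(g) for g in report.or_groups],
        "objective_counts": list(report.objective_counts),
        "nitrogen_carriers": list(report.nitrogen_carriers),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "report.txt").write_text(report.to_text())
    return out
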