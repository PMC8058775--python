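"""Top-level linting entry point and machine-readable results.

``lint`` ties the checks together in the order moiety -> LP -> GAMES,
mirroring how a software linter runs a configurable battery of
independent checks.  GAMES is only invoked when LP analysis reports an
inconsistency — isolation is pointless for a consistent network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .bgames import IsolationReport
from .lp import LPResult, LPStatus, detect_inconsistency_lp
from .moiety import (
    MoietyImbalance,
    MoietyStructure,
    check_moiety_balance,
    make_moiety_structure,
    render_moiety_report,
)
from .network import AnalysisConfig, ReactionNetwork, build_stoichiometry_matrix
from .xgames import GamesOutcome, games

__all__ = ["LintResult", "lint", "lint_network", "load_network"]

EXIT_CLEAN = 0
EXIT_FINDINGS = 1
EXIT_ERROR = 2

ALL_CHECKS = ("moiety", "lp", "games")


@dataclass
class LintResult:
    """Everything one lint run found for one model."""

    model_id: str
    checks: tuple[str, ...]
    moiety_imbalances: list[MoietyImbalance] = field(default_factory=list)
    moiety_structure: MoietyStructure | None = None
    moiety_report_text: str = ""
    lp_result: LPResult | None = None
    games_outcome: GamesOutcome | None = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def isolation(self) -> IsolationReport | None:
        if self.games_outcome is None:
            return None
        return self.games_outcome.report

    @property
    def has_findings(self) -> bool:
        if self.moiety_imbalances:
            return True
        if self.lp_result is not None and not self.lp_result.is_consistent:
            return True
        return False

    @property
    def exit_code(self) -> int:
        if self.lp_result is not None and self.lp_result.status == LPStatus.SOLVER_ERROR:
            return EXIT_ERROR
        return EXIT_FINDINGS if self.has_findings else EXIT_CLEAN

    def to_dict(self) -> dict:
        def frac(x: Fraction):
            return (
                int(x)
                if x.denominator == 1
                else {"num": x.numerator, "den": x.denominator}
            )

        out: dict = {
            "model_id": self.model_id,
            "checks": list(self.checks),
            "diagnostics": list(self.diagnostics),
            "findings": self.has_findings,
        }
        if "moiety" in self.checks:
            out["moiety_imbalances"] = [
                {
                    "reaction_id": imb.reaction_id,
                    "deltas": {m: frac(d) for m, d in imb.deltas.items()},
                }
                for imb in self.moiety_imbalances
            ]
        if self.lp_result is not None:
            out["lp_status"] = self.lp_result.status
            if self.lp_result.mass_vector is not None:
                out["mass_vector"] = self.lp_result.mass_vector
        if self.games_outcome is not None:
            out["games"] = self.games_outcome.to_dict()
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def load_network(path: str | Path) -> ReactionNetwork:
    """Load a model from SBML (.xml/.sbml) or the plain-text dialect."""
    from .io import read_reaction_file, read_sbml

    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(path)
    return read_reaction_file(path)


def lint_network(
    net: ReactionNetwork,
    config: AnalysisConfig | None = None,
    checks: tuple[str, ...] = ALL_CHECKS,
    moiety_names: set[str] | None = None,
    structure: MoietyStructure | None = None,
) -> LintResult:
    """Run the requested checks on an in-memory network.

    ``moiety`` needs either an explicit structure or a moiety-name list
    to resolve species against; it is skipped (with a diagnostic) when
    neither is given.  ``games`` runs only when ``lp`` found an
    inconsistency.
    """
    config = config or AnalysisConfig()
    unknown = set(checks) - set(ALL_CHECKS)
    if unknown:
        raise ValueError(f"unknown checks: {sorted(unknown)}")
    result = LintResult(model_id=net.name or "<network>", checks=tuple(checks))

    if "moiety" in checks:
        if structure is None and moiety_names:
            structure = make_moiety_structure(net, moiety_names, config)
        if structure is None:
            result.diagnostics.append(
                "moiety check skipped: no moiety names or structure given"
            )
        else:
            result.moiety_structure = structure
            for sid in getattr(structure, "unresolved", []):
                result.diagnostics.append(
                    f"species {sid!r} has no moiety decomposition"
                )
            imbalances, diags = check_moiety_balance(net, structure, config)
            result.moiety_imbalances = imbalances
            result.moiety_report_text = render_moiety_report(
                imbalances, net, structure
            )
            result.diagnostics.extend(diags)

    if "lp" in checks or "games" in checks:
        matrix = build_stoichiometry_matrix(net, config)
        result.lp_result = detect_inconsistency_lp(matrix)
        if result.lp_result.status == LPStatus.SOLVER_ERROR:
            result.diagnostics.append(f"lp: {result.lp_result.message}")

    if "games" in checks and result.lp_result is not None:
        if result.lp_result.is_consistent:
            result.diagnostics.append(
                "games skipped: LP analysis reports consistency"
            )
        else:
            result.games_outcome = games(net, config)
    return result


def lint(
    path: str | Path,
    config: AnalysisConfig | None = None,
    checks: tuple[str, ...] = ALL_CHECKS,
    moiety_names: set[str] | None = None,
    structure: MoietyStructure | None = None,
) -> LintResult:
    """Load a model file and lint it; see :func:`lint_network`."""
    net = load_network(path)
    return lint_network(
        net,
        config=config,
        checks=checks,
        moiety_names=moiety_names,
        structure=structure,
    )


def render_lint_report(result: LintResult) -> str:
    """Deterministic human-readable report across all requested checks."""
    lines = [f"model: {result.model_id}"]
    if "moiety" in result.checks and result.moiety_report_text:
        lines.append("")
        lines.append("== moiety analysis ==")
        lines.append(result.moiety_report_text.rstrip())
    if result.lp_result is not None:
        lines.append("")
        lines.append(f"== LP analysis: {result.lp_result.status} ==")
        if result.lp_result.mass_vector:
            witness = ", ".join(
                f"{sid}={val:g}"
                for sid, val in sorted(result.lp_result.mass_vector.items())
            )
            lines.append(f"mass witness: {witness}")
    if result.games_outcome is not None:
        lines.append("")
        lines.append(f"== GAMES: {result.games_outcome.verdict} ==")
        if result.games_outcome.report is not None:
            rep = result.games_outcome.report
            lines.append(f"method: {rep.method}")
            lines.append(f"RIS: {', '.join(rep.ris)}")
            lines.append(f"SIS: {', '.join(rep.sis)}")
            lines.extend(rep.narrative)
    for diag in result.diagnostics:
        lines.append(f"note: {diag}")
    return "\n".join(lines) + "\n"
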