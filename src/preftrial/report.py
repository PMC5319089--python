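"""Flat, serialisable analysis reports combining estimation, inference and
assumption checks."""

from __future__ import annotations

from importlib import metadata

from . import assumptions, estimation, inference
from .errors import UndefinedContrastError
from .trial_data import TrialSummary


def _version() -> str:
    try:
        return metadata.version("preftrial")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def analyze_summary(
    s: TrialSummary, method: str = "conditional", level: float = 0.95
) -> dict:
    """Full analysis of one trial summary as a JSON-ready dict.

    Reports every estimable contrast with SE, z, p and CI under the chosen
    variance method.  The second contrasts have no closed-form unconditional
    variance, so under ``method="unconditional"`` they are reported with
    conditional SEs and flagged as such.
    """
    effects = []
    for which in estimation.EFFECTS:
        use = method
        try:
            res = inference.test_contrast(s, which, method=use, level=level)
        except UndefinedContrastError:
            if method == "unconditional" and which.endswith("2"):
                try:
                    res = inference.test_contrast(s, which, method="conditional", level=level)
                except UndefinedContrastError:
                    continue
            else:
                continue
        effects.append(res.to_dict())
    checks = assumptions.assumption_table(s).to_dict(orient="records") if s.m3 > 0 else []
    return {
        "package": "preftrial",
        "version": _version(),
        "design": {
            "m1": s.m1, "m2": s.m2, "m3": s.m3,
            "n13": s.n13, "n23": s.n23, "n1": s.n1, "n2": s.n2,
            "alpha_hat": s.alpha_hat, "beta_hat": s.beta_hat,
            "gamma_hat": s.gamma_hat, "theta_hat": s.theta_hat,
            "pooled_sd": inference.pooled_sd(s),
        },
        "method": method,
        "level": level,
        "effects": effects,
        "assumption_checks": checks,
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`analyze_summary` output (the same
    numbers, formatted)."""
    lines = [
        f"preftrial {report['version']} — two-stage preference trial analysis",
        f"method: {report['method']}   CI level: {report['level']:.0%}",
        (
            "design: m={m}  (choosers A/B: {m1}/{m2}, undecided: {m3}),  "
            "random arm: {n1}/{n2}".format(
                m=report["design"]["m1"] + report["design"]["m2"] + report["design"]["m3"],
                **report["design"],
            )
        ),
        f"pooled SD: {report['design']['pooled_sd']:.4g}",
        "",
        f"{'effect':<14}{'estimate':>10}{'SE':>9}{'z':>8}{'p':>8}   CI",
    ]
    for e in report["effects"]:
        lines.append(
            f"{e['effect']:<14}{e['estimate']:>10.3f}{e['se']:>9.3f}"
            f"{e['z']:>8.2f}{e['p']:>8.3f}   "
            f"({e['ci_low']:.2f}, {e['ci_high']:.2f})"
            + ("   [conditional SE]" if e["method"] != report["method"] else "")
        )
    if report["assumption_checks"]:
        lines += ["", "assumption checks (undecided stratum):",
                  f"{'assumption':<24}{'trt':>4}{'diff':>9}{'z':>8}{'p':>8}"]
        for c in report["assumption_checks"]:
            lines.append(
                f"{c['assumption']:<24}{c['treatment']:>4}"
                f"{c['difference']:>9.3f}{c['z']:>8.2f}{c['p']:>8.3f}"
            )
    return "\n".join(lines)
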