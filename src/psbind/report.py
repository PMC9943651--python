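"""Markdown report rendering for binding fits and stereo calls."""

from __future__ import annotations

from .binding import BindingFit
from .stereo import StereoCall, summarize_calls
from .structanalysis import Contact


def render_report(
    fits: list[tuple[BindingFit, dict]] | None = None,
    calls: list[StereoCall] | None = None,
    contacts: list[Contact] | None = None,
    provenance: dict | None = None,
) -> str:
    """One markdown document with a table per analysis."""
    fits = fits or []
    calls = calls or []
    contacts = contacts or []
    if not (fits or calls or contacts):
        raise ValueError("need at least one result object to report")
    lines = ["# psbind analysis report", ""]
    if provenance:
        lines.append("## Provenance")
        lines.append("")
        for k, v in provenance.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if fits:
        lines += [
            "## Binding fits",
            "",
            "| oligo | condition | K_D (μM) | ± SE | A0 | ΔA | NS | model | AIC | n |",
            "|---|---|---|---|---|---|---|---|---|---|",
        ]
        for fit, record in fits:
            se = fit.std_errors.get("k_d", float("nan"))
            lines.append(
                f"| {fit.oligo or '-'} | {fit.condition or '-'} "
                f"| {fit.params.k_d:.3g} | {se:.2g} "
                f"| {fit.params.a0:.4f} | {fit.params.da:.4f} "
                f"| {fit.params.ns:.4f} | {record.get('selected', '-')} "
                f"| {fit.aic:.1f} | {fit.n_points} |"
            )
        lines.append("")
    if calls:
        lines += [
            "## Stereo calls",
            "",
            "| linkage | chain | res5-res3 | call | Rp peak (σ) | Sp peak (σ) | mean B (Å²) | reliable |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for c in calls:
            lines.append(
                f"| PS{c.linkage_id} | {c.chain} | {c.res5}-{c.res3} | {c.call} "
                f"| {c.peak_rp_sigma:.1f} | {c.peak_sp_sigma:.1f} "
                f"| {c.b_factor:.0f} | {c.reliable} |"
            )
        counts = summarize_calls(calls)
        lines.append("")
        lines.append(
            "Summary: "
            + ", ".join(f"{k}: {v}" for k, v in counts.items() if v)
        )
        lines.append("")
    if contacts:
        lines += [
            "## Contacts",
            "",
            "| pair | distance (Å) | kind |",
            "|---|---|---|",
        ]
        for c in contacts:
            lines.append(f"| {c.pair_label} | {c.distance:.2f} | {c.kind} |")
        lines.append("")
    return "\n".join(lines)
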