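"""Bundled reference data.

Published replica-level MM/GBSA + interaction-entropy summaries for
three PCSK9–inhibitor complexes (ligands SBC-115076, RIm13, and
AK-968/12164422), each simulated in three independent replicas under
both an additive force-field charge model ("amber") and polarized
protein-specific charges ("ppc").  Columns are ΔE_vdW, ΔE_ele, ΔG_gb,
ΔG_np, ΔH, −TΔS, ΔG_bind with their standard errors, all kcal/mol.

These rows exercise the replica-averaging and bookkeeping machinery on
real published numbers; the printed Average rows are retained
separately so computed averages can be checked against them.
"""

from __future__ import annotations

from .free_energy import FreeEnergySummary

__all__ = ["pcsk9_replica_rows", "pcsk9_published_average", "SYSTEMS"]

SYSTEMS = (("sbc", "amber"), ("sbc", "ppc"), ("rim", "amber"),
           ("rim", "ppc"), ("ak", "amber"), ("ak", "ppc"))

# (e_vdw, e_ele, g_gb, g_np, dh, minus_tds, dg) and matching SEMs
_ROWS = {
    ("sbc", "amber"): [
        ((-23.21, -20.72, 26.85, -2.36, -19.43, 15.97, -3.46),
         (0.16, 0.25, 0.16, 0.01, 0.11, 0.55, 0.33)),
        ((-23.24, -19.95, 26.09, -2.29, -19.38, 16.09, -3.29),
         (0.16, 0.24, 0.13, 0.01, 0.11, 0.38, 0.24)),
        ((-28.08, -20.77, 30.66, -2.70, -20.89, 25.95, 5.06),
         (0.15, 0.59, 0.42, 0.01, 0.17, 0.56, 0.37)),
    ],
    ("sbc", "ppc"): [
        ((-36.22, -27.99, 40.06, -3.29, -27.44, 8.63, -18.81),
         (0.20, 0.17, 0.14, 0.02, 0.14, 0.29, 0.21)),
        ((-20.51, -23.45, 27.09, -2.25, -19.11, 14.57, -4.54),
         (0.14, 0.16, 0.12, 0.01, 0.10, 0.59, 0.34)),
        ((-22.60, -35.96, 38.14, -2.48, -22.89, 12.39, -10.50),
         (0.15, 0.20, 0.14, 0.01, 0.12, 0.57, 0.34)),
    ],
    ("rim", "amber"): [
        ((-28.83, -26.81, 59.51, -2.37, 1.50, 42.55, 44.05),
         (0.17, 0.49, 0.56, 0.01, 0.15, 0.59, 0.37)),
        ((-26.08, -15.52, 43.28, -2.08, -0.40, 50.48, 50.08),
         (0.18, 0.59, 0.67, 0.01, 0.16, 0.54, 0.35)),
        ((-29.28, -16.61, 50.96, -2.46, 2.62, 48.65, 51.27),
         (0.23, 0.56, 0.53, 0.02, 0.26, 0.48, 0.37)),
    ],
    ("rim", "ppc"): [
        ((-26.64, -11.02, 24.11, -2.59, -16.13, 10.51, -5.62),
         (0.15, 0.14, 0.16, 0.02, 0.11, 0.57, 0.34)),
        ((-34.39, -9.08, 29.81, -3.16, -16.83, 13.48, -3.35),
         (0.17, 0.21, 0.22, 0.01, 0.12, 0.51, 0.32)),
        ((-33.26, -13.86, 27.01, -2.95, -23.07, 21.85, -1.22),
         (0.25, 0.19, 0.20, 0.02, 0.23, 0.50, 0.36)),
    ],
    ("ak", "amber"): [
        ((-26.00, -28.67, 42.42, -2.39, -14.65, 24.79, 10.14),
         (0.12, 0.38, 0.34, 0.01, 0.11, 0.48, 0.30)),
        ((-35.80, -33.01, 48.15, -3.31, -23.96, 28.41, 4.45),
         (0.15, 0.43, 0.40, 0.01, 0.17, 0.59, 0.38)),
        ((-24.58, -55.48, 52.01, -2.43, -30.48, 37.82, 7.34),
         (0.17, 0.56, 0.48, 0.01, 0.21, 0.59, 0.40)),
    ],
    ("ak", "ppc"): [
        ((-26.72, -42.13, 45.72, -2.29, -25.43, 23.43, -1.99),
         (0.15, 0.48, 0.43, 0.01, 0.15, 0.42, 0.29)),
        ((-26.69, -56.91, 58.96, -2.79, -27.43, 23.71, -3.72),
         (0.17, 0.37, 0.31, 0.01, 0.17, 0.35, 0.26)),
        ((-33.89, -40.74, 49.17, -3.23, -28.69, 17.08, -11.61),
         (0.16, 0.35, 0.31, 0.01, 0.15, 0.42, 0.29)),
    ],
}

_AVERAGES = {
    ("sbc", "amber"): ((-24.84, -20.48, 27.87, -2.45, -19.90, 19.34, -0.56),
                       (0.16, 0.36, 0.24, 0.01, 0.13, 0.50, 0.31)),
    ("sbc", "ppc"): ((-26.44, -29.13, 35.10, -2.67, -23.15, 11.86, -11.28),
                     (0.16, 0.18, 0.13, 0.01, 0.12, 0.48, 0.30)),
    ("rim", "amber"): ((-28.06, -19.64, 51.25, -2.30, 1.24, 47.23, 48.47),
                       (0.19, 0.54, 0.59, 0.01, 0.19, 0.54, 0.36)),
    ("rim", "ppc"): ((-31.43, -11.32, 26.98, -2.90, -18.67, 15.28, -3.39),
                     (0.19, 0.18, 0.19, 0.02, 0.15, 0.53, 0.34)),
    ("ak", "amber"): ((-28.80, -39.05, 47.53, -2.71, -23.03, 30.34, 7.31),
                      (0.15, 0.46, 0.41, 0.01, 0.16, 0.55, 0.36)),
    ("ak", "ppc"): ((-29.10, -46.59, 51.28, -2.77, -27.18, 21.41, -5.77),
                    (0.16, 0.40, 0.35, 0.01, 0.16, 0.40, 0.28)),
}


def _summary(values, sems, label) -> FreeEnergySummary:
    cols = FreeEnergySummary.COLUMNS
    kwargs = dict(zip(cols, values))
    kwargs.update({f"sem_{c}": s for c, s in zip(cols, sems)})
    return FreeEnergySummary(label=label, **kwargs)


def pcsk9_replica_rows(system: str, charge_model: str
                       ) -> list[FreeEnergySummary]:
    """Replica rows for one complex/charge-model block."""
    rows = _ROWS[(system, charge_model)]
    return [_summary(v, s, f"No. {i + 1}") for i, (v, s) in enumerate(rows)]


def pcsk9_published_average(system: str, charge_model: str
                            ) -> FreeEnergySummary:
    """The printed Average row for one block (for cross-checks)."""
    v, s = _AVERAGES[(system, charge_model)]
    return _summary(v, s, "Average")
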