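"""Published summary numbers of the motivating six-route campaign.

A mobile PM2.5 monitoring study around La Carolina Park (Quito, Ecuador)
walked six routes — three parallel to the park (X1, X2, X3) and three
perpendicular to it (Y1, Y2, Y3) — with a portable light-scattering
monitor. The raw series were never deposited; only summary tables were
published. The printed per-route sample sizes, medians and 95%
order-statistic confidence limits for the median are embedded here: they
parameterise the synthetic study preset and serve as fixed inputs for the
classification and group-comparison worked examples.

All concentrations are mg/m3.
"""

from __future__ import annotations

ROUTE_IDS = ("X1", "X2", "X3", "Y1", "Y2", "Y3")

#: group label per route: X = parallel to the park, Y = perpendicular
GROUP_OF = {r: r[0] for r in ROUTE_IDS}

#: published per-route sample sizes
ROUTE_COUNTS = {
    "X1": 156,
    "X2": 83,
    "X3": 102,
    "Y1": 70,
    "Y2": 70,
    "Y3": 82,
}

#: published per-route sample medians (mg/m3)
ROUTE_MEDIANS = {
    "X1": 0.0360,
    "X2": 0.0370,
    "X3": 0.0095,
    "Y1": 0.0085,
    "Y2": 0.0330,
    "Y3": 0.0450,
}

#: published 95% order-statistic confidence limits for the median
#: (lower, upper), mg/m3
ROUTE_MEDIAN_CI = {
    "X1": (0.034, 0.037),
    "X2": (0.036, 0.038),
    "X3": (0.006, 0.013),
    "Y1": (0.004, 0.019),
    "Y2": (0.025, 0.034),
    "Y3": (0.038, 0.057),
}

#: instrument calibration check: applied and indicated concentration
#: (mg/m3) from the manufacturer's wind-tunnel certificate
CALIBRATION_APPLIED = 4.94
CALIBRATION_INDICATED = 4.91
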