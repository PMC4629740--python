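"""Shared constants: oxidative-potential metrics, units, and site typology."""

#: Oxidative potential assay metrics handled by the pipeline.
#: OP_DTT — dithiothreitol consumption rate; OP_ESR — electron spin resonance
#: hydroxyl-radical signal (DMPO-OH quartet amplitude).
METRICS = ("OP_DTT", "OP_ESR")

#: Measurement units per metric (value per m3 of sampled air).
METRIC_UNITS = {
    "OP_DTT": "nmol DTT/min/m3",
    "OP_ESR": "A.U./m3",
}

#: Monitoring-site typology: regional background, urban background, street.
SITE_TYPES = ("RB", "UB", "S")

SITE_TYPE_LABELS = {
    "RB": "regional background",
    "UB": "urban background",
    "S": "street",
}


def check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return metric


def check_site_type(site_type: str) -> str:
    if site_type not in SITE_TYPES:
        raise ValueError(
            f"unknown site type {site_type!r}; expected one of {SITE_TYPES}"
        )
    return site_type
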