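"""Reference inputs shipped with the package.

``BASELINE_TABLE`` holds the printed baseline cross-tabulations of the
59-patient gastric adenocarcinoma immunotherapy cohort, stratified by
presence of tertiary lymphoid structures in the tumour core (columns:
TLS−, TLS+). These printed counts are *inputs*: the package recomputes
the group-comparison p-values from them with
:func:`tlsscape.stats.chi_square_table`.

``REPORTED_SURVIVAL`` holds the cohort's published survival headline
values as reference metadata only. They were estimated from patient-level
follow-up data that is not publicly deposited, so this package cannot
recompute them; they are flagged ``source="reported"`` and are never
returned by any computation.
"""

from __future__ import annotations

from types import MappingProxyType

from .stats import ContingencyTable

#: Variable -> ContingencyTable of printed counts (rows: categories,
#: columns: TLS−, TLS+). "Unknown" rows are included where the printed
#: group-comparison used them (tumour differentiation) and excluded where
#: it did not (Lauren classification); both raw variants are shipped.
BASELINE_TABLE = MappingProxyType(
    {
        "age": ContingencyTable(
            ((17, 20), (9, 13)),
            row_labels=("<65", ">=65"),
            column_labels=("TLS-", "TLS+"),
        ),
        "gender": ContingencyTable(
            ((20, 25), (6, 8)),
            row_labels=("Male", "Female"),
            column_labels=("TLS-", "TLS+"),
        ),
        "stage": ContingencyTable(
            ((1, 1), (2, 1), (5, 6), (18, 25)),
            row_labels=("I", "II", "III", "IV"),
            column_labels=("TLS-", "TLS+"),
        ),
        "differentiation": ContingencyTable(
            ((6, 1), (13, 9), (6, 21), (1, 2)),
            row_labels=("High", "Moderate", "Poor", "Unknown"),
            column_labels=("TLS-", "TLS+"),
        ),
        "lauren": ContingencyTable(
            ((13, 11), (6, 9), (5, 13)),
            row_labels=("Intestinal", "Mixed", "Diffused"),
            column_labels=("TLS-", "TLS+"),
        ),
        "lauren_with_unknown": ContingencyTable(
            ((13, 11), (6, 9), (5, 13), (2, 0)),
            row_labels=("Intestinal", "Mixed", "Diffused", "Unknown"),
            column_labels=("TLS-", "TLS+"),
        ),
        "location": ContingencyTable(
            ((14, 23), (12, 10)),
            row_labels=("GEJ", "Non-GEJ"),
            column_labels=("TLS-", "TLS+"),
        ),
        "her2": ContingencyTable(
            ((7, 5), (19, 28)),
            row_labels=("Positive", "Negative"),
            column_labels=("TLS-", "TLS+"),
        ),
        "microsatellite": ContingencyTable(
            ((5, 2), (21, 31)),
            row_labels=("MSI", "MSS"),
            column_labels=("TLS-", "TLS+"),
        ),
    }
)

#: Published survival headline values for the same cohort. Reference
#: metadata only: the underlying patient-level times are not deposited,
#: so these numbers are not recomputable and are never produced by this
#: package's estimators.
REPORTED_SURVIVAL = MappingProxyType(
    {
        "irOS_tls_negative_median_months": {"value": 30.3, "source": "reported"},
        "irOS_tls_logrank_p": {"value": 0.049, "source": "reported"},
        "irOS_tls_hr": {"value": 0.37, "source": "reported"},
        "OS_low_dss_median_months": {"value": 26.20, "source": "reported"},
        "OS_high_dss_median_months": {"value": 16.02, "source": "reported"},
        "OS_dss_logrank_p": {"value": 0.0033, "source": "reported"},
        "OS_dss_hr": {"value": 0.40, "source": "reported"},
    }
)
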