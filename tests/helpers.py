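"""Shared test helpers (not a test module)."""

import numpy as np

from prsopt.io import AggregatedResponse, DoseCombination


def agg_from(doses, values, panel, context="FA-free", endpoint="viability_pct"):
    """Build AggregatedResponse rows directly from (n, d) doses and values."""
    out = []
    for d, v in zip(np.asarray(doses, dtype=float), values):
        out.append(
            AggregatedResponse(
                dose=DoseCombination.from_mapping(
                    {a.name: float(x) for a, x in zip(panel, d)}
                ),
                context=context,
                endpoint_name=endpoint,
                mean_value=float(v),
                n_bio=1,
                per_bio_values=(float(v),),
            )
        )
    return out
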