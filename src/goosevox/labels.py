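"""The closed set of flock behaviours.

Three behaviours are recognised: *flushing* (geese take off en masse),
*landing* (a flock approaches and settles) and *foraging* (geese on the
ground picking food).  The class order below is the canonical ordering used
by confusion matrices and by the pairwise classification graph.
"""

from .errors import ValidationError

FLUSHING = "flushing"
LANDING = "landing"
FORAGING = "foraging"

#: Canonical class order: rows/columns of confusion matrices, DAG root pair.
CLASS_ORDER = (FLUSHING, LANDING, FORAGING)


def validate_label(value: str) -> str:
    """Return ``value`` if it is one of the three behaviour labels."""
    if value not in CLASS_ORDER:
        raise ValidationError(
            f"unknown behaviour label {value!r}; expected one of {CLASS_ORDER}"
        )
    return value
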