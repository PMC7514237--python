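"""Packaged example datasets."""

from importlib import resources

from ..data import IntervalMatrix, read_interval_csv

__all__ = ["load_faces"]


def load_faces() -> IntervalMatrix:
    """The faces morphometry dataset: 27 cases × 6 interval variables.

    Each case is a sequence of images of one face; the six variables are
    pixel distances between facial landmarks (eye span, inter-eye distance,
    eye-to-lip and lip-to-mouth distances), aggregated over the sequence
    into intervals.  Cases are labelled FRA1…ROM3 (nine subjects, three
    sequences each).
    """
    with resources.as_file(resources.files(__package__) / "faces.csv") as path:
        return read_interval_csv(path, dialect="bracket")
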