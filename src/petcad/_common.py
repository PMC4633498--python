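"""Shared label encoding and error types.

Label convention used throughout the package: idiopathic Parkinson's disease
(PD) is the positive class and is encoded as 1; atypical parkinsonian
syndromes (APS: MSA + PSP pooled) are the negative class, encoded as 0.
"""

from __future__ import annotations

LABEL_PD: int = 1
LABEL_APS: int = 0

LABEL_NAMES = {LABEL_PD: "PD", LABEL_APS: "APS"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}


class PetcadError(Exception):
    """Base class for package errors."""


class ConfigurationError(PetcadError):
    """Invalid phantom or pipeline configuration."""


class NormalizationError(PetcadError):
    """Intensity normalization cannot be performed (e.g. all-zero volume)."""


class InferenceError(PetcadError):
    """Bayesian-network inference failed (zero total probability)."""
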