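"""Sign conventions and categorical codes shared by every module.

All spatial quantities are in degrees of visual angle, rightward positive.
The spatial disparity is ``delta = eps_a - eps_v`` (auditory minus visual):
positive delta means the auditory stimulus is to the right of the visual one.
For the audio-visual synchrony experiment, delta is in milliseconds and
positive delta means the visual stimulus led the auditory one.

Response codes:

* implicit (localization) tasks: ``+1`` rightward, ``-1`` leftward;
* explicit common-cause report: ``1`` common source, ``2`` separate sources;
* synchrony judgment: ``1`` synchronous, ``2`` asynchronous.

The "positive" code of each task (rightward / common / synchronous) is the
one favored by the lapse bias.
"""

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5")

CONDITIONS = ("auditory_only", "visual_only", "audio_visual")

RELIABILITIES = ("high", "medium", "low")

#: Response codes, per experiment kind.
RIGHT, LEFT = 1, -1
COMMON, SEPARATE = 1, 2
SYNCHRONOUS, ASYNCHRONOUS = 1, 2

#: Legal response codes for each experiment.
RESPONSE_CODES = {
    "exp1": (RIGHT, LEFT),
    "exp2": (RIGHT, LEFT),
    "exp3": (COMMON, SEPARATE),
    "exp4": (SYNCHRONOUS, ASYNCHRONOUS),
}

#: The lapse-favored response code per experiment, and its alternative.
POSITIVE_CODE = {"exp1": RIGHT, "exp2": RIGHT, "exp3": COMMON, "exp4": SYNCHRONOUS}
NEGATIVE_CODE = {"exp1": LEFT, "exp2": LEFT, "exp3": SEPARATE, "exp4": ASYNCHRONOUS}

#: Columns of the canonical trial table (CSV schema).
TRIAL_COLUMNS = (
    "experiment",
    "condition",
    "eps_a",
    "eps_v",
    "reliability",
    "delta",
    "repetition",
)

RESPONSE_COLUMNS = TRIAL_COLUMNS + ("response", "subject_id", "group")


def delta_of(eps_a: float, eps_v: float) -> float:
    """Signed spatial disparity under the package convention."""
    return eps_a - eps_v
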