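"""Shared numeric conventions of the visual water task.

The 70%-correct criterion, the 2AFC guess rate, and the staircase step
sizes are the task's defining constants and are used across modules.
"""

# Two-alternative forced choice: chance performance.
GUESS_RATE = 0.5

# Threshold criterion: a stimulus level is "seen" when accuracy reaches 70%.
ACCURACY_CRITERION = 0.70

# Default lapse rate: leaves near-perfect (>= 90%) performance attainable on
# easy stimuli, as required during the shaping phase of the task.
DEFAULT_LAPSE = 0.02

# Staircase step sizes.
CONTRAST_STEP = 0.10          # Michelson contrast units
SF_STEP = 0.03                # cycles per degree

# Assessment starting levels (easiest stimulus in each domain).
CONTRAST_START = 1.0          # 100% contrast
SF_START = 0.12               # cpd; the shaping-phase spatial frequency

# Criterion test: pass on 4 consecutive correct, or 7 correct within a
# block of 10 consecutive trials; fail otherwise at block completion.
CRITERION_STREAK = 4
CRITERION_HITS = 7
BLOCK_SIZE = 10

TRIALS_PER_SESSION = 10
SESSIONS_PER_DAY = 2

# Physical caps for the level grids.
SF_MAX = 1.5                  # cpd; above any mouse acuity
CONTRAST_MIN = 0.01
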