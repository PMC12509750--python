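"""The closed-form study metrics on example measurements."""

from adductscreen.study_metrics import (
    recognition_index,
    spontaneous_alternation,
    tumor_volume,
)

# xenograft caliper measurements (mm): V = 0.5 x L x W^2
print(f"tumor 10 x 5 mm -> {tumor_volume(10, 5):.1f} mm^3")

# Y-maze: 10 correct alternations out of 22 arm entries
print(f"spontaneous alternation: {spontaneous_alternation(10, 22):.1f} %")

# novel-object recognition: 42 s on the novel vs 28 s on the familiar object
print(f"recognition index: {recognition_index(42, 28):.3f}")
# 0.5 means no preference; above 0.5 indicates intact recognition memory.
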