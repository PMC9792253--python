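"""Per-layer accounting for the lightweight 1-D CNN.

Builds the reference inverted-residual architecture for 1024-sample
single-channel windows and prints the per-layer table with output
shapes, parameter counts and multiply-adds, then the totals the model
is sized by (2.2 M parameters, about 92.5 M mult-adds).
"""

from eegsmote import (build_model, count_mult_adds, count_parameters,
                      default_spec, summary_table)

spec = default_spec()
graph = build_model(spec)
print(summary_table(graph))
print()
print(f"shape flow (length x channels): "
      f"{' -> '.join(f'{L}x{C}' for L, C in spec.shape_flow())}")
print(f"totals: {count_parameters(graph):,d} parameters, "
      f"{count_mult_adds(graph):,d} mult-adds at input length "
      f"{spec.input_length}")
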