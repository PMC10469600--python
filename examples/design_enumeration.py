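"""Enumerate the dual-reporter experimental design for the built-in panel.

The panel holds 15 reporter genes; sublancin (sunA) is excluded because
its reporter strain alters colony morphology.  Every unordered pair of
the remaining genes is built in both fluorophore orientations.
"""

from dualreporter.panel import default_panel, enumerate_design

panel = default_panel()
design = enumerate_design(panel)

print(f"active genes: {panel.n_active}  ({', '.join(panel.active_genes)})")
print(f"unordered pairs: {design.n_pairs}")
print(f"strain configurations (both color orientations): {design.n_configurations}")
print()
print(design.to_frame().head(6).to_string(index=False))
print()
print("Each row is one strain: the pair, and which gene drives YPet vs mTurq.")
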