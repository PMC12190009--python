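"""Tabular assay computations: SOCE, DNA normalisation, XBP1 splicing.

A store-operated calcium entry (SOCE) trace follows the readdition
protocol (5 min Ca2+-free wash, 30 min store depletion, Ca2+ readdition,
sampling every 5 s); its summary is the post-readdition peak over the
pre-readdition baseline. Metabolic readouts divide by DNA content; ER
stress is the spliced fraction of XBP1 bands.
"""

from ermech_quant import assays, synthetic

trace, truth = synthetic.gen_soce_trace(
    baseline_F=1.0, peak_F=2.8, noise_sd=0.02, seed=3
)
v = assays.soce_normalized_max(trace, smoothing="mean3")
print(f"SOCE normalised max: {v:.3f} (ground truth "
      f"{truth.parameters['normalized_max_truth']:.3f}) — "
      f"peak Ca2+ influx relative to the depleted-store baseline")

ocr = [182.0, 240.0, 150.0]          # raw oxygen-consumption readouts
dna = [95.0, 130.0, 80.0]            # ng DNA per construct
norm = assays.normalize_by_dna(ocr, dna)
print("OCR per ng DNA:", [round(float(x), 3) for x in norm],
      "— removes construct-size differences")

ratio = assays.xbp1_splicing_ratio(assays.SplicingBands(u_intensity=70, s_intensity=30))
print(f"XBP1 spliced fraction: {ratio:.2f} "
      f"(spliced / total; higher means more ER stress)")
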