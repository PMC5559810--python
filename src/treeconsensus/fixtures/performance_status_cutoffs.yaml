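schema_version: "1"
# Performance-status encodings as initially collected from six centers,
# before harmonization onto the shared binary fitness criterion.
records:
  - center: A
    scale: KPS
    cutoff: 50
    levels: ["<50", ">=50"]
  - center: B
    scale: KPS
    cutoff: 60
    levels: ["<60", ">=60"]
  - center: C
    scale: KPS
    cutoff: 70
    levels: ["<70", ">=70"]
  - center: D
    scale: KPS
    cutoff: 90
    levels: ["<90", ">=90"]
  - center: E
    scale: ECOG
    cutoff: 1
    levels: ["<=1", ">1"]
  - center: F
    scale: null
    cutoff: null
    levels: [good, bad]
    note: no specific scale; good/bad mapped 1:1 onto fit/unfit by moderation
harmonized_criteria:
  - name: fitness
    levels: [fit, unfit]
    description: harmonized binary performance status
rules:
  - source: performance_status
    target: fitness
    participants: [A]
    source_scale: KPS
    cutoff: 50
    map: {"<50": unfit, ">=50": fit}
  - source: performance_status
    target: fitness
    participants: [B]
    source_scale: KPS
    cutoff: 60
    map: {"<60": unfit, ">=60": fit}
  - source: performance_status
    target: fitness
    participants: [C]
    source_scale: KPS
    cutoff: 70
    map: {"<70": unfit, ">=70": fit}
  - source: performance_status
    target: fitness
    participants: [D]
    source_scale: KPS
    cutoff: 90
    map: {"<90": unfit, ">=90": fit}
  - source: performance_status
    target: fitness
    participants: [E]
    source_scale: ECOG
    cutoff: 1
    map: {"<=1": fit, ">1": unfit}
  - source: performance_status
    target: fitness
    participants: [F]
    map: {good: fit, bad: unfit}
    note: no numeric scale; 1:1 mapping fixed during moderation
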