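e44014bc445af43bca1f8d5cb4a19c9fb152133f50920014be2e00a049785b71  panel_41_cohort.tsv
a934f1a3b1709b17ccd4ca39e4c8fae21f63d524b41ad2caa113cb4131ebca1c  cohort_patients.tsv
f8a929a8c0d6b8d010556f8967e549d2cc5bcd0b2ce1488d5fbcdb2ad64276a9  cohort_variants.tsv
d08bcf998d7d26f0fc2e31e08bf2663bd5513c33572254e40e1639f6decf69f7  interaction_edges.tsv
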