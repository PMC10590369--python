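# Example theme map for a 17-topic model (topic indices are 0-based).
# Five named themes typical of teaching work on a course platform; every
# topic not listed here falls into the implicit "Others" theme.
themes:
  Evaluation: [8, 16]
  Courses: [3, 9, 11]
  Progress tracking: [2, 14]
  Situation tracking: [0, 6, 12]
  Final grading: [15]
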