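n_actors: 30
n_weeks: 22
n_clusters: 3
vocabulary:
- object_00>updated
- object_01>created
- object_02>deleted
- object_03>graded
- object_04>viewed
- object_05>submitted
- object_06>updated
- object_07>created
- object_08>deleted
- object_09>graded
- object_10>viewed
- object_11>submitted
- object_12>updated
- object_13>created
- object_14>deleted
- object_15>graded
- object_16>viewed
- object_17>submitted
- object_18>updated
- object_19>created
- object_20>deleted
- object_21>graded
- object_22>viewed
- object_23>submitted
- object_24>updated
- object_25>created
- object_26>deleted
- object_27>graded
- object_28>viewed
- object_29>submitted
- object_30>updated
- object_31>created
- object_32>deleted
- object_33>graded
- object_34>viewed
- object_35>submitted
- course>viewed
- course_module>viewed
- notification>sent
- notification>viewed
- user>loggedin
- user>loggedout
n_topics_true: 6
theme_map_true:
  0: theme_1
  1: theme_1
  2: theme_2
  3: theme_2
  4: theme_3
  5: theme_3
trajectory_spec:
  0:
    theme_1:
    - - 1.0
      - 0.7999999999999999
    - - 22.0
      - 0.9
    theme_2:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
    theme_3:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
  1:
    theme_1:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
    theme_2:
    - - 1.0
      - 0.7999999999999999
    - - 22.0
      - 0.9
    theme_3:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
  2:
    theme_1:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
    theme_2:
    - - 1.0
      - 0.1
    - - 22.0
      - 0.05000000000000001
    theme_3:
    - - 1.0
      - 0.7999999999999999
    - - 22.0
      - 0.9
events_per_week_mean: 120.0
events_per_week_dispersion: 2.0
general_use_rate: 0.25
low_activity_week_prob: 0.05
seed: 7
start_year: 2019
topic_word: null
general_tokens:
- course>viewed
- course_module>viewed
- notification>sent
- notification>viewed
- user>loggedin
- user>loggedout
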