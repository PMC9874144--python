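# Default subscale key for the 39-item Five Facet Mindfulness Questionnaire,
# following the published FFMQ-39 item assignment.  Items marked reverse are
# scored 6 - response before summation.  Edit a copy of this file to use a
# different keying (e.g. a translated form with altered item order).
items:
  item_01: {subscale: observing, reverse: false}
  item_02: {subscale: describing, reverse: false}
  item_03: {subscale: nonjudgment, reverse: true}
  item_04: {subscale: nonreactivity, reverse: false}
  item_05: {subscale: acting_with_awareness, reverse: true}
  item_06: {subscale: observing, reverse: false}
  item_07: {subscale: describing, reverse: false}
  item_08: {subscale: acting_with_awareness, reverse: true}
  item_09: {subscale: nonreactivity, reverse: false}
  item_10: {subscale: nonjudgment, reverse: true}
  item_11: {subscale: observing, reverse: false}
  item_12: {subscale: describing, reverse: true}
  item_13: {subscale: acting_with_awareness, reverse: true}
  item_14: {subscale: nonjudgment, reverse: true}
  item_15: {subscale: observing, reverse: false}
  item_16: {subscale: describing, reverse: true}
  item_17: {subscale: nonjudgment, reverse: true}
  item_18: {subscale: acting_with_awareness, reverse: true}
  item_19: {subscale: nonreactivity, reverse: false}
  item_20: {subscale: observing, reverse: false}
  item_21: {subscale: nonreactivity, reverse: false}
  item_22: {subscale: describing, reverse: true}
  item_23: {subscale: acting_with_awareness, reverse: true}
  item_24: {subscale: nonreactivity, reverse: false}
  item_25: {subscale: nonjudgment, reverse: true}
  item_26: {subscale: observing, reverse: false}
  item_27: {subscale: describing, reverse: false}
  item_28: {subscale: acting_with_awareness, reverse: true}
  item_29: {subscale: nonreactivity, reverse: false}
  item_30: {subscale: nonjudgment, reverse: true}
  item_31: {subscale: observing, reverse: false}
  item_32: {subscale: describing, reverse: false}
  item_33: {subscale: nonreactivity, reverse: false}
  item_34: {subscale: acting_with_awareness, reverse: true}
  item_35: {subscale: nonjudgment, reverse: true}
  item_36: {subscale: observing, reverse: false}
  item_37: {subscale: describing, reverse: false}
  item_38: {subscale: acting_with_awareness, reverse: true}
  item_39: {subscale: nonjudgment, reverse: true}
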