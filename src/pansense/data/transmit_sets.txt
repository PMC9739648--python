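# Reference transmit-set configurations for the four-position PAN.
# One line per configuration: main,<supports separated by spaces>,<one
# bracketed 0/1 vector per support, ';'-separated, supports' order>.
# Vector position j follows the canonical activity order:
# walking, jogging, squats, jump, lying, arms_swing, sitting, standing.
s1,s2,[1, 1, 0, 1, 1, 1, 1, 0]
s1,s3,[1, 0, 0, 0, 1, 1, 1, 0]
s1,s4,[1, 1, 0, 1, 1, 1, 1, 0]
s1,s2 s3,[1, 0, 0, 0, 0, 1, 0, 0];[1, 0, 0, 0, 1, 1, 1, 0]
s1,s2 s4,[1, 0, 0, 0, 0, 1, 1, 0];[1, 1, 0, 1, 1, 1, 1, 0]
s1,s3 s4,[1, 0, 0, 0, 0, 1, 1, 0];[1, 1, 0, 1, 1, 1, 1, 0]
s1,s2 s3 s4,[1, 0, 0, 0, 0, 0, 0, 0];[1, 0, 0, 0, 0, 1, 1, 0];[1, 1, 0, 1, 1, 1, 1, 0]
s2,s1,[1, 1, 0, 1, 1, 1, 0, 1]
s2,s3,[1, 0, 0, 1, 1, 1, 1, 1]
s2,s4,[1, 1, 0, 1, 1, 1, 1, 1]
s2,s1 s3,[1, 1, 0, 1, 1, 0, 0, 0];[1, 1, 0, 1, 1, 1, 1, 1]
s2,s1 s4,[0, 1, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 1, 1]
s2,s3 s4,[1, 1, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 1, 1]
s2,s1 s3 s4,[0, 1, 0, 0, 0, 0, 0, 0];[1, 0, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 1, 1]
s3,s1,[1, 1, 0, 1, 1, 1, 0, 0]
s3,s2,[1, 1, 0, 1, 1, 1, 1, 0]
s3,s4,[1, 1, 0, 1, 1, 1, 0, 0]
s3,s1 s2,[0, 0, 0, 1, 1, 1, 0, 0];[1, 1, 0, 1, 1, 1, 1, 0]
s3,s1 s4,[1, 1, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 0, 0]
s3,s2 s4,[1, 1, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 0, 0]
s3,s1 s2 s4,[0, 0, 0, 0, 0, 0, 0, 0];[1, 1, 0, 0, 0, 1, 0, 0];[1, 1, 0, 1, 1, 1, 0, 0]
s4,s1,[1, 1, 1, 0, 0, 1, 1, 1]
s4,s2,[1, 1, 1, 0, 0, 1, 1, 1]
s4,s3,[1, 1, 1, 0, 0, 1, 1, 1]
s4,s1 s2,[1, 1, 0, 0, 0, 0, 0, 0];[1, 1, 1, 0, 0, 1, 1, 1]
s4,s1 s3,[1, 1, 0, 0, 0, 0, 0, 0];[1, 1, 1, 0, 0, 1, 1, 1]
s4,s2 s3,[1, 1, 0, 0, 0, 0, 0, 0];[1, 1, 1, 0, 0, 1, 1, 1]
s4,s1 s2 s3,[1, 0, 0, 0, 0, 0, 0, 0];[1, 1, 0, 0, 0, 0, 0, 0];[1, 1, 1, 0, 0, 1, 1, 1]
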