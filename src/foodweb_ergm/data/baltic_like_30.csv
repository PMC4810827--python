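prey,predator
sp00,sp02
sp00,sp04
sp00,sp08
sp00,sp09
sp00,sp10
sp00,sp12
sp00,sp19
sp00,sp20
sp00,sp25
sp01,sp06
sp01,sp07
sp01,sp11
sp01,sp12
sp01,sp13
sp01,sp21
sp01,sp24
sp02,sp01
sp02,sp05
sp02,sp06
sp02,sp07
sp02,sp12
sp02,sp16
sp02,sp21
sp02,sp24
sp03,sp01
sp03,sp02
sp03,sp04
sp03,sp05
sp03,sp06
sp03,sp07
sp03,sp12
sp03,sp16
sp03,sp21
sp03,sp23
sp03,sp24
sp04,sp06
sp04,sp07
sp04,sp13
sp04,sp21
sp05,sp13
sp06,sp13
sp07,sp06
sp07,sp13
sp07,sp21
sp08,sp06
sp08,sp13
sp08,sp21
sp09,sp01
sp09,sp06
sp09,sp07
sp09,sp11
sp09,sp12
sp09,sp16
sp09,sp21
sp09,sp24
sp10,sp01
sp10,sp02
sp10,sp04
sp10,sp05
sp10,sp06
sp10,sp07
sp10,sp12
sp10,sp16
sp10,sp21
sp10,sp23
sp10,sp24
sp11,sp06
sp11,sp07
sp11,sp12
sp11,sp13
sp11,sp15
sp11,sp21
sp11,sp24
sp12,sp06
sp12,sp07
sp12,sp11
sp12,sp13
sp12,sp21
sp12,sp24
sp14,sp01
sp14,sp05
sp14,sp06
sp14,sp07
sp14,sp12
sp14,sp16
sp14,sp21
sp14,sp24
sp15,sp06
sp15,sp07
sp15,sp11
sp15,sp12
sp15,sp13
sp15,sp21
sp15,sp24
sp16,sp01
sp16,sp05
sp16,sp06
sp16,sp07
sp16,sp12
sp16,sp21
sp16,sp24
sp17,sp02
sp17,sp04
sp17,sp08
sp17,sp10
sp17,sp12
sp17,sp19
sp17,sp20
sp17,sp25
sp18,sp03
sp18,sp17
sp18,sp27
sp18,sp29
sp19,sp01
sp19,sp02
sp19,sp04
sp19,sp05
sp19,sp06
sp19,sp07
sp19,sp09
sp19,sp10
sp19,sp12
sp19,sp20
sp19,sp21
sp19,sp25
sp20,sp06
sp20,sp07
sp20,sp11
sp20,sp12
sp20,sp13
sp20,sp21
sp20,sp24
sp21,sp06
sp21,sp13
sp22,sp03
sp22,sp17
sp23,sp01
sp23,sp06
sp23,sp07
sp23,sp11
sp23,sp12
sp23,sp16
sp23,sp21
sp23,sp24
sp24,sp06
sp24,sp13
sp24,sp21
sp25,sp13
sp26,sp02
sp26,sp04
sp26,sp08
sp26,sp09
sp26,sp10
sp26,sp12
sp26,sp19
sp26,sp20
sp26,sp25
sp27,sp00
sp27,sp03
sp27,sp12
sp27,sp29
sp28,sp02
sp28,sp04
sp28,sp08
sp28,sp10
sp28,sp12
sp28,sp19
sp28,sp20
sp28,sp25
sp29,sp01
sp29,sp02
sp29,sp04
sp29,sp05
sp29,sp06
sp29,sp07
sp29,sp12
sp29,sp16
sp29,sp21
sp29,sp23
sp29,sp24
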