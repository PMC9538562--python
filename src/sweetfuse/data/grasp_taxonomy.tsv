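gesture_id	gesture_name	object_name
1	Medium wrap	Bottle
1	Medium wrap	Can
1	Medium wrap	Door handle
1	Medium wrap	Mug
2	Lateral	Key
2	Lateral	Pencil case
2	Lateral	Plate
3	Parallel extension	Book
3	Parallel extension	Drawer
3	Parallel extension	Bottle
4	Tripod grasp	Mug
4	Tripod grasp	Drawer
4	Tripod grasp	Ball
5	Power sphere	Bulb
5	Power sphere	Key
5	Power sphere	Jar
6	Precision disk	Bulb
6	Precision disk	Ball
6	Precision disk	Clothespin
7	Prismatic pinch	Key
7	Prismatic pinch	Can
7	Prismatic pinch	Remote
8	Index finger extension	Knife
8	Index finger extension	Fork
8	Index finger extension	Screwdriver
9	Adducted thumb	Remote
9	Adducted thumb	Wrench
9	Adducted thumb	Knife
10	Prismatic four finger	Fork
10	Prismatic four finger	Wrench
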