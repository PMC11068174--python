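format_version,boundary,side,order,x,y
1,AB,upper,0,0,50
1,AB,upper,1,30,50
1,AB,upper,2,140,170
1,AB,upper,3,280,380
1,AB,upper,4,430,550
1,AB,lower,0,50,0
1,AB,lower,1,50,30
1,AB,lower,2,170,145
1,AB,lower,3,385,300
1,AB,lower,4,550,450
1,BC,upper,0,0,60
1,BC,upper,1,30,60
1,BC,upper,2,50,80
1,BC,upper,3,70,110
1,BC,upper,4,260,550
1,BC,lower,0,120,0
1,BC,lower,1,120,30
1,BC,lower,2,260,130
1,BC,lower,3,550,250
1,CD,upper,0,0,100
1,CD,upper,1,25,100
1,CD,upper,2,50,125
1,CD,upper,3,80,215
1,CD,upper,4,125,550
1,CD,lower,0,250,0
1,CD,lower,1,250,40
1,CD,lower,2,550,150
1,DE,upper,0,0,150
1,DE,upper,1,35,155
1,DE,upper,2,50,550
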